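"""Cohort orchestration: run every method over a cohort and report agreement.

`run_cohort` drives the full comparison on synthetic subjects: for each
phantom it simulates observers (seeded smooth contour jitter plus whole-pixel
ROI-seed jitter — the only user inputs the semi-automated methods have),
quantifies IS on LGE with FWHM / 5-8SD / Otsu and AAR on T2w with 2SD /
Otsu, adds repeated manual analyses whose mean forms the reference standard,
and assembles a long-format RatingsTable. `reproduce_supplementary` turns
any such table (generated here or ingested from external raw data via the
column-mapping loader) into the method-comparison report: per-method mean,
ICC and Bland-Altman bias versus the manual reference, and interobserver /
intraobserver agreement blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, quantify, stats
from .io import ContourSet, ImageStack, SliceContours, validate_ratings, write_ratings
from .phantom import PhantomSpec, core_seed, generate_phantom, remote_seed

__all__ = [
    "PipelineError",
    "SubjectEntry",
    "CohortConfig",
    "run_cohort",
    "reproduce_supplementary",
]

IS_METHODS = ("FWHM", "5SD", "6SD", "7SD", "8SD", "OAT")
AAR_METHODS = ("2SD", "OAT")
REFERENCE_METHOD = "manual"


class PipelineError(RuntimeError):
    """A subject failed quantification; no silent skips."""


@dataclass
class SubjectEntry:
    subject_id: str
    spec: PhantomSpec
    lvef: float | None = None  # metadata only; never computed here


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort run."""

    subjects: list[SubjectEntry]
    measures: tuple[str, ...] = ("IS", "AAR")
    field_strength: str = "1.5T"
    n_observers: int = 2
    n_replicates: int = 2
    n_manual_observers: int = 3  # reference = mean of 3 observers x 2 replicates
    contour_jitter_px: float = 0.4
    roi_jitter_px: float = 1.5
    manual_jitter_pct: float = 1.0
    roi_area_cm2: float = geometry.DEFAULT_ROI_AREA_CM2
    apical_exclusion: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, payload: dict) -> "CohortConfig":
        subjects = [
            SubjectEntry(
                subject_id=s["subject_id"],
                spec=PhantomSpec(**s.get("spec", {})),
                lvef=s.get("lvef"),
            )
            for s in payload.pop("subjects")
        ]
        return cls(subjects=subjects, **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _jitter_contours(
    contours: ContourSet, rng: np.random.Generator, amplitude_px: float
) -> ContourSet:
    """Smooth low-order radial perturbation of each polygon (observer re-draw).

    Amplitudes of three angular harmonics are drawn per contour, so the
    perturbed polygon stays simple (no vertex-level noise).
    """
    if amplitude_px <= 0:
        return contours
    out: dict[int, SliceContours] = {}
    for idx, sc in contours.slices.items():
        polys = {}
        for name in ("endo", "epi"):
            poly = np.asarray(getattr(sc, name), float)
            centre = poly.mean(axis=0)
            rel = poly - centre
            radius = np.hypot(rel[:, 0], rel[:, 1])
            ang = np.arctan2(rel[:, 0], rel[:, 1])
            delta = np.zeros_like(radius)
            for h in (1, 2, 3):
                amp = rng.normal(0.0, amplitude_px / h)
                phase = rng.uniform(0, 2 * np.pi)
                delta += amp * np.sin(h * ang + phase)
            new_r = np.maximum(radius + delta, 1.0)
            polys[name] = centre + np.column_stack(
                [new_r * np.sin(ang), new_r * np.cos(ang)]
            )
        out[idx] = SliceContours(endo=polys["endo"], epi=polys["epi"])
    return ContourSet(slices=out)


def _snap_to_myocardium(
    myo: geometry.MyoMask, slice_index: int, seed: tuple[float, float]
) -> tuple[int, int]:
    """Nearest myocardial pixel to the requested seed on that slice."""
    sl = myo.mask[slice_index]
    r0, c0 = int(round(seed[0])), int(round(seed[1]))
    r0 = min(max(r0, 0), sl.shape[0] - 1)
    c0 = min(max(c0, 0), sl.shape[1] - 1)
    if sl[r0, c0]:
        return r0, c0
    rows, cols = np.nonzero(sl)
    if len(rows) == 0:
        raise PipelineError(f"slice {slice_index} has no myocardium")
    d2 = (rows - r0) ** 2 + (cols - c0) ** 2
    j = int(np.argmin(d2))
    return int(rows[j]), int(cols[j])


def _measure_subject_variant(
    stack_lge: ImageStack,
    stack_t2w: ImageStack,
    contours: ContourSet,
    truth,
    spec: PhantomSpec,
    config: CohortConfig,
    rng: np.random.Generator,
    measures: tuple[str, ...],
) -> tuple[dict[tuple[str, str], float], dict]:
    """One observer-replicate analysis: returns {(measure, method): %LVM}."""
    jittered = _jitter_contours(contours, rng, config.contour_jitter_px)
    myo = geometry.rasterize(jittered, stack_lge)
    if config.apical_exclusion:
        myo = geometry.exclude_apical_slice(myo)

    values: dict[tuple[str, str], float] = {}
    provenance: dict = {}

    for measure in measures:
        stack = stack_lge if measure == "IS" else stack_t2w
        methods = IS_METHODS if measure == "IS" else AAR_METHODS
        sl, r, c = remote_seed(spec)
        r += rng.normal(0.0, config.roi_jitter_px)
        c += rng.normal(0.0, config.roi_jitter_px)
        rr, cc = _snap_to_myocardium(myo, sl, (r, c))
        remote = geometry.build_roi(
            myo, stack, sl, (rr, cc), target_area_cm2=config.roi_area_cm2,
            avoid_rim_px=1,
        )
        for method in methods:
            if method == "FWHM":
                res = quantify.quantify_stack(stack, myo, "fwhm")
            elif method == "OAT":
                res = quantify.quantify_stack(stack, myo, "otsu")
            elif method.endswith("SD"):
                res = quantify.quantify_stack(
                    stack, myo, "ksd", remote_roi=remote, k=float(method[:-2])
                )
            else:  # pragma: no cover - guarded by module constants
                raise PipelineError(f"unknown method {method}")
            values[(measure, method)] = res.percent_lvm
            provenance[f"{measure}:{method}"] = {
                "thresholds": [None if np.isnan(t) else t for t in res.thresholds],
                "corrections": list(res.corrections_applied),
            }
    return values, provenance


def _manual_value(
    truth, myo: geometry.MyoMask, measure: str, rng: np.random.Generator, jitter_pct: float
) -> float:
    """Manual (visual) analysis: ground-truth lesion within the observer's
    contours, plus a small seeded visual-judgement jitter."""
    lesion = truth.infarct_mask if measure == "IS" else truth.oedema_mask
    q = myo.quantifiable_volume()
    denom = int(q.sum())
    if denom == 0:
        raise PipelineError("empty myocardium in manual analysis")
    pct = 100.0 * int((lesion & q).sum()) / denom
    pct += rng.normal(0.0, jitter_pct)
    return float(np.clip(pct, 0.0, 100.0))


def run_cohort(config: CohortConfig, out_dir: str | Path | None = None):
    """Run the full comparison over a cohort of phantoms.

    Returns ``(ratings, reports, provenance)``: the long-format RatingsTable,
    a dict of per-measure report DataFrames (plus an IS-vs-LVEF correlation
    table when LVEF metadata is supplied), and a provenance log of
    thresholds and corrections. Deterministic given the config seed.
    """
    rows: list[dict] = []
    provenance: dict = {"config_seed": config.seed, "subjects": {}}
    n_manual = max(config.n_manual_observers, config.n_observers)

    for i, entry in enumerate(config.subjects):
        try:
            spec = replace(entry.spec, seed=int(np.random.SeedSequence(
                [config.seed, i]).generate_state(1)[0] % (2**31)))
            lge, t2w, contours, truth = generate_phantom(spec)
            sub_prov: dict = {
                "true_is": truth.true_is_percent_lvm,
                "true_aar": truth.true_aar_percent_lvm,
                "analyses": {},
            }
            for o in range(n_manual):
                for rep in range(1, config.n_replicates + 1):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([config.seed, i, o, rep])
                    )
                    rater = f"R{o + 1}"
                    do_methods = o < config.n_observers
                    if do_methods:
                        vals, prov = _measure_subject_variant(
                            lge, t2w, contours, truth, spec, config, rng,
                            config.measures,
                        )
                        sub_prov["analyses"][f"{rater}:rep{rep}"] = prov
                        for (measure, method), value in vals.items():
                            rows.append(
                                {
                                    "subject": entry.subject_id,
                                    "field_strength": config.field_strength,
                                    "measure": measure,
                                    "method": method,
                                    "rater": rater,
                                    "replicate": rep,
                                    "value": float(np.clip(value, 0.0, 100.0)),
                                }
                            )
                    # manual analyses for every manual observer (incl. extra expert)
                    jit = _jitter_contours(contours, rng, config.contour_jitter_px)
                    myo = geometry.rasterize(jit, lge)
                    if config.apical_exclusion:
                        myo = geometry.exclude_apical_slice(myo)
                    for measure in config.measures:
                        rows.append(
                            {
                                "subject": entry.subject_id,
                                "field_strength": config.field_strength,
                                "measure": measure,
                                "method": REFERENCE_METHOD,
                                "rater": rater,
                                "replicate": rep,
                                "value": _manual_value(
                                    truth, myo, measure, rng, config.manual_jitter_pct
                                ),
                            }
                        )
            provenance["subjects"][entry.subject_id] = sub_prov
        except Exception as exc:
            raise PipelineError(f"subject {entry.subject_id}: {exc}") from exc

    ratings = validate_ratings(pd.DataFrame(rows))
    reports = reproduce_supplementary(ratings)

    lvefs = {e.subject_id: e.lvef for e in config.subjects}
    if all(v is not None for v in lvefs.values()) and "IS" in config.measures:
        reports["lvef_correlation"] = _lvef_correlation(ratings, lvefs, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ratings(ratings, out / "ratings.csv")
        for key, df in reports.items():
            name = key if isinstance(key, str) else "report_" + "_".join(key).replace(
                ".", "p"
            )
            df.to_csv(out / f"{name.lower()}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return ratings, reports, provenance


def _lvef_correlation(
    ratings: pd.DataFrame, lvefs: dict[str, float], config: CohortConfig
) -> pd.DataFrame:
    primary = ratings[
        (ratings["measure"] == "IS")
        & (ratings["rater"] == "R1")
        & (ratings["replicate"] == 1)
    ]
    rows = []
    for method, grp in primary.groupby("method"):
        grp = grp.sort_values("subject")
        is_vals = grp["value"].to_numpy()
        ef_vals = np.array([lvefs[s] for s in grp["subject"]])
        try:
            r, p = stats.pearson(is_vals, ef_vals)
        except stats.StatsError:
            r, p = np.nan, np.nan
        rows.append({"method": method, "pearson_r": r, "p": p, "n": len(grp)})
    return pd.DataFrame(rows)


def _pivot(df: pd.DataFrame, rater: str, replicate: int) -> pd.Series:
    sel = df[(df["rater"] == rater) & (df["replicate"] == replicate)]
    return sel.set_index("subject")["value"]


def reproduce_supplementary(
    ratings: pd.DataFrame, reference_method: str = REFERENCE_METHOD
) -> dict:
    """Method-comparison report from a long-format raw measurement table.

    For every (field strength, measure) block: per-method mean +/- SD over
    subjects (first rater, first replicate), ICC / Bland-Altman bias / paired
    t versus the reference (the per-subject mean of all the reference
    method's analyses), and interobserver (rater 1 vs 2, replicate 1) and
    intraobserver (rater 1, replicate 1 vs 2) agreement blocks where the
    table contains them. Returns ``{(field_strength, measure): DataFrame}``.
    """
    ratings = validate_ratings(ratings)
    reports: dict = {}
    for (fs, measure), block in ratings.groupby(["field_strength", "measure"]):
        methods = sorted(block["method"].unique())
        has_reference = reference_method in methods
        reference = None
        if has_reference:
            reference = (
                block[block["method"] == reference_method]
                .groupby("subject")["value"]
                .mean()
            )
        out_rows = []
        for method in methods:
            sub = block[block["method"] == method]
            raters = sorted(sub["rater"].unique())
            reps = sorted(sub["replicate"].unique())
            primary = _pivot(sub, raters[0], reps[0]).sort_index()
            row: dict = {
                "method": method,
                "n": len(primary),
                "mean": primary.mean(),
                "sd": primary.std(ddof=1),
            }
            if has_reference and method != reference_method:
                ref = reference.reindex(primary.index)
                if ref.isna().any():
                    raise stats.StatsError(
                        f"reference '{reference_method}' missing for some subjects"
                    )
                rep = stats.agreement_report(primary.to_numpy(), ref.to_numpy())
                row.update(
                    icc_v_ref=rep.icc,
                    icc_category=rep.icc_category,
                    bias=rep.bias,
                    loa_low=rep.loa_low,
                    loa_high=rep.loa_high,
                    t_p=rep.paired_t_p,
                )
            if len(raters) >= 2:
                a = _pivot(sub, raters[0], reps[0]).sort_index()
                b = _pivot(sub, raters[1], reps[0]).reindex(a.index)
                rep = stats.agreement_report(a.to_numpy(), b.to_numpy())
                row.update(
                    interobs_icc=rep.icc,
                    interobs_bias=rep.bias,
                    interobs_loa_low=rep.loa_low,
                    interobs_loa_high=rep.loa_high,
                )
            if len(reps) >= 2:
                a = _pivot(sub, raters[0], reps[0]).sort_index()
                b = _pivot(sub, raters[0], reps[1]).reindex(a.index)
                rep = stats.agreement_report(a.to_numpy(), b.to_numpy())
                row.update(
                    intraobs_icc=rep.icc,
                    intraobs_bias=rep.bias,
                    intraobs_loa_low=rep.loa_low,
                    intraobs_loa_high=rep.loa_high,
                )
            out_rows.append(row)
        reports[(fs, measure)] = pd.DataFrame(out_rows)
    return reports
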