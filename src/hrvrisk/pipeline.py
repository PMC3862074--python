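"""End-to-end orchestration: records -> features -> screening -> set search.

``run_extract`` filters each tachogram, applies the >10%-ectopy
exclusion rule and computes every HRV index on the four analysis
segments (24 h, first 30 min, most stationary 30 min of day and of
night); the segmented short-term symbolic dynamics family is computed on
the 24-h segment only.  ``run_stats`` then screens every index per
segment, prunes correlated candidates and searches the optimal
five-index discriminant sets for the four composition classes.
Per-record or per-segment failures produce missing values, never abort
the run; records with missing values are dropped listwise within each
index-set evaluation.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fractal_poincare, linear_hrv, symbolic_dynamics
from .errors import HRVError, InfeasibleCompositionError
from .io_preprocess import (
    DAY_WINDOW,
    NIGHT_WINDOW,
    NNSeries,
    Tachogram,
    adaptive_nn_filter,
    exclusion_check,
    extract_clock_window,
    first_30min,
    most_stationary_30min,
    read_tachogram,
)
from .risk_stats import (
    CLINICAL_INDICES,
    COMPOSITIONS,
    optimal_set_search,
    pearson_prune,
    screen,
)

__all__ = [
    "RunConfig",
    "SEGMENTS",
    "segment_record",
    "compute_segment_indices",
    "extract_record_features",
    "run_extract",
    "run_stats",
]

log = logging.getLogger("hrvrisk")

SEGMENTS = ("h24", "first30", "day30", "night30")


@dataclass
class RunConfig:
    """All tunable parameters of one analysis run."""

    # cohort generation
    n_lr: int = 221
    n_hr: int = 35
    contrast: float = 1.0
    duration_s: float = 86400.0
    seed: int = 0
    # preprocessing
    rel_tol: float = 0.20
    abs_tol_ms: float = 50.0
    max_ectopy: float = 0.10
    # symbolic dynamics
    sd_alpha: float = 0.1
    binary_limit_ms: float = 5.0
    sdsd_a: float = 1.0
    sdsd_tau: int = 1
    sdsd_M: int = 5
    # fractal / Poincare
    dfa_short: tuple = (4, 16)
    dfa_long: tuple = (16, 64)
    sppa_grid: int = 12
    # statistics
    sig_level: float = 0.05
    adj_level: float = 0.01
    r_threshold: float = 0.7
    max_nonclinical_pool: int = 10
    compositions: tuple = ("clinical", "nonclinical", "mixed1", "mixed2")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                raw[k.strip()] = v.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "compositions":
                kwargs[f.name] = tuple(v.split(","))
            elif f.name in ("dfa_short", "dfa_long"):
                kwargs[f.name] = tuple(int(x) for x in v.split(","))
            elif f.type == "int" or f.name in ("n_lr", "n_hr", "seed", "sdsd_tau",
                                               "sdsd_M", "sppa_grid",
                                               "max_nonclinical_pool"):
                kwargs[f.name] = int(v)
            else:
                kwargs[f.name] = float(v)
        return cls(**kwargs)


def segment_record(nn: NNSeries) -> dict:
    """Slice one filtered record into the four analysis segments.

    Missing segments (short record, clock window not covered) are
    omitted from the result rather than raised.
    """
    segments: dict[str, NNSeries] = {"h24": nn}
    try:
        segments["first30"] = first_30min(nn)
    except HRVError as e:
        log.warning("first30 unavailable: %s", e)
    for label, window in (("day30", DAY_WINDOW), ("night30", NIGHT_WINDOW)):
        try:
            four_h = extract_clock_window(nn, *window)
            seg, _ = most_stationary_30min(four_h, label=label)
            segments[label] = seg
        except HRVError as e:
            log.warning("%s unavailable: %s", label, e)
    return segments


def compute_segment_indices(seg: NNSeries, cfg: RunConfig, with_ssd: bool) -> dict:
    """Every HRV index for one segment; failed methods yield no keys."""
    out: dict[str, float] = {}
    try:
        out.update(linear_hrv.time_domain_indices(seg))
    except HRVError:
        pass
    try:
        sp = linear_hrv.power_spectrum(seg)
        out.update(linear_hrv.frequency_indices(sp))
    except HRVError:
        pass
    try:
        sym = symbolic_dynamics.encode_classical(seg, alpha=cfg.sd_alpha)
        hist = symbolic_dynamics.word_histogram(sym)
        out.update(symbolic_dynamics.classical_sd_indices(hist))
    except HRVError:
        pass
    try:
        out.update(symbolic_dynamics.binary_variability_patterns(seg, cfg.binary_limit_ms))
    except HRVError:
        pass
    try:
        out.update(symbolic_dynamics.stsd(seg).aggregates)
    except HRVError:
        pass
    try:
        out["tau1_p001"] = symbolic_dynamics.sdsd(
            seg, a=cfg.sdsd_a, tau=cfg.sdsd_tau, M=cfg.sdsd_M
        )["tau1_p001"]
    except HRVError:
        pass
    try:
        prof = fractal_poincare.dfa(seg, cfg.dfa_short, cfg.dfa_long)
        out["alpha1"] = prof.alpha1
        if prof.alpha2 is not None:
            out["alpha2"] = prof.alpha2
    except HRVError:
        pass
    try:
        mat = fractal_poincare.sppa(seg, grid=cfg.sppa_grid)
        out["SPPA_entropy"] = mat.entropy_bits
        for i in range(cfg.sppa_grid):
            out[f"SPPA_r_{i + 1}"] = float(mat.row_probs[i])
            out[f"SPPA_c_{i + 1}"] = float(mat.col_probs[i])
    except HRVError:
        pass
    if with_ssd:
        try:
            ssd = symbolic_dynamics.ssd_24h(seg, alpha=cfg.sd_alpha)
            ssd.pop("S_windows", None)
            out.update(ssd)
        except HRVError:
            pass
    return out


def extract_record_features(nn: NNSeries, cfg: RunConfig) -> dict:
    """Segment one record and compute indices per segment (SSD on h24 only)."""
    out = {}
    for label, seg in segment_record(nn).items():
        t0 = time.perf_counter()
        out[label] = compute_segment_indices(seg, cfg, with_ssd=(label == "h24"))
        log.info("record segment=%s n_beats=%d indices=%d dt=%.2fs",
                 label, len(seg), len(out[label]), time.perf_counter() - t0)
    return out


def _load_input(item, cfg: RunConfig) -> tuple[str, NNSeries]:
    """Accept a SyntheticRecord, (id, Tachogram/NNSeries) pair or a file path."""
    if hasattr(item, "tachogram"):  # SyntheticRecord
        rid, payload = item.record_id, item.tachogram
    elif isinstance(item, tuple):
        rid, payload = item
    else:
        path = Path(item)
        rid = path.stem
        payload = read_tachogram(path, format="csv" if path.suffix == ".csv" else "plain")
    if isinstance(payload, Tachogram):
        payload = adaptive_nn_filter(payload, cfg.rel_tol, cfg.abs_tol_ms)
    return rid, payload


def run_extract(inputs, cfg: RunConfig) -> dict:
    """Feature tables per segment for a list of records.

    ``inputs`` may hold synthetic records, (id, tachogram) pairs or file
    paths.  Records failing the ectopy exclusion rule are dropped and
    listed under ``"excluded"``.  Returns
    ``{"features": {segment: DataFrame(id x index)}, "excluded": [...]}``.
    """
    rows: dict[str, dict] = {s: {} for s in SEGMENTS}
    excluded = []
    for item in inputs:
        rid, nn = _load_input(item, cfg)
        if exclusion_check(nn, cfg.max_ectopy):
            log.info("record %s excluded: ectopy %.1f%%", rid, 100 * nn.ectopy_fraction)
            excluded.append(rid)
            continue
        for label, vals in extract_record_features(nn, cfg).items():
            rows[label][rid] = vals
    features = {
        s: pd.DataFrame.from_dict(rows[s], orient="index").sort_index()
        for s in SEGMENTS
        if rows[s]
    }
    if not features:
        raise HRVError(f"no valid records (excluded: {excluded})")
    return {"features": features, "excluded": excluded}


def _candidate_pools(merged: pd.DataFrame, screening: pd.DataFrame,
                     cfg: RunConfig) -> tuple[list, list]:
    """Pruned significant candidates, split clinical vs non-clinical.

    Pools too small for the requested compositions are topped up with
    the best-ranked remaining candidates (ascending p), so a feasible
    composition is never starved by borderline significance alone.
    """
    pvals = screening["p"].to_dict()
    usable = [c for c in screening.index
              if np.isfinite(pvals.get(c, np.nan))]
    sig = [c for c in usable if pvals[c] < cfg.sig_level]
    pruned = pearson_prune(merged, sig, cfg.r_threshold, p_values=pvals)

    def split(cols):
        clin = [c for c in cols if c in CLINICAL_INDICES]
        non = [c for c in cols if c not in CLINICAL_INDICES]
        return clin, non

    clin, non = split(pruned)
    need_clin = max(n for n, _ in (COMPOSITIONS[c] for c in cfg.compositions))
    need_non = max(n for _, n in (COMPOSITIONS[c] for c in cfg.compositions))
    if len(clin) < need_clin or len(non) < need_non:
        rest = sorted((c for c in usable if c not in pruned),
                      key=lambda c: (pvals[c], c))
        extra = pearson_prune(merged, rest, cfg.r_threshold, p_values=pvals)
        rc, rn = split(extra)
        clin += rc[: max(0, need_clin - len(clin))]
        non += rn[: max(0, need_non - len(non))]
    non = sorted(non, key=lambda c: (pvals[c], c))[: cfg.max_nonclinical_pool]
    return clin, non


def run_stats(features: dict, cohort: pd.DataFrame, cfg: RunConfig) -> dict:
    """Screening tables and optimal-set reports per segment.

    ``features`` maps segment label to a DataFrame indexed by record id;
    ``cohort`` carries id, group and the clinical covariates.  Raises on
    ids present in the features but absent from the cohort table.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    out: dict = {"screening": {}, "classification": [], "pools": {}}
    for label, feats in features.items():
        orphans = feats.index.difference(cohort.index)
        if len(orphans):
            raise HRVError(f"feature ids missing from cohort table: {list(orphans)}")
        merged = feats.join(cohort, how="inner")
        feature_cols = [c for c in feats.columns] + list(CLINICAL_INDICES)
        screening = screen(merged, feature_cols)
        out["screening"][label] = screening
        clin_pool, non_pool = _candidate_pools(merged, screening, cfg)
        out["pools"][label] = {"clinical": clin_pool, "nonclinical": non_pool}
        for comp in cfg.compositions:
            try:
                rep = optimal_set_search(merged, clin_pool, non_pool, comp)
                row = {"segment": label, **rep.as_dict(),
                       "n_evaluated": rep.n_evaluated}
            except InfeasibleCompositionError as e:
                row = {"segment": label, "composition": comp, "error": str(e)}
            out["classification"].append(row)
    out["classification"] = pd.DataFrame(out["classification"])
    return out
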