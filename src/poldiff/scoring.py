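"""AP-MS differential interaction scoring.

The scheme quantifies how a mutated bait changes its interactome relative to
the wild-type bait, using spectral counts from paired affinity purifications
and an empty-vector (EV) background control:

1.  zeros (proteins identified in some runs but not others) are replaced,
    per run, by draws from a normal distribution fitted to the lowest 20% of
    that run's nonzero counts — the run's background-noise floor;
2.  counts in bait-containing runs are normalized by the bait's own count so
    purifications of different efficiency are comparable;
3.  high-confidence interactors are proteins identified in every replicate
    of at least one arm (WT or MUT) whose mean count exceeds the EV mean by
    more than a fivefold ratio, strictly;
4.  for each high-confidence interactor a two-tailed one-sample t-test is
    run on the per-pair MUT/WT count ratios against the null ratio 1;
5.  p-values are Benjamini–Hochberg adjusted, and a protein is called
    differential only when the adjusted p is below alpha AND the mean fold
    change clears a symmetric gate (>1.5 or <1/1.5).

The order of operations matters: imputation happens on raw counts per run
(so every downstream ratio is finite), normalization after, and the
"identified in all replicates" presence rule is evaluated on the raw,
pre-imputation counts — an imputed zero is background noise, not an
identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DesignError,
    ImputationError,
    NormalizationError,
    TestError,
    ValidationError,
)
from .io import IMPUTED, NORMALIZED, RAW, RunDesign, SpectralCountTable

__all__ = [
    "ScoringConfig",
    "InteractorSummary",
    "DifferentialResult",
    "LABEL_DECREASED",
    "LABEL_INCREASED",
    "LABEL_NOT_SIGNIFICANT",
    "LABEL_NOT_TESTED",
    "analysis_universe",
    "normalize_by_bait",
    "impute_zero_counts",
    "flag_high_confidence",
    "differential_interaction_test",
    "adjust_bh",
    "classify_interactions",
    "build_display_matrix",
    "analyze_variant",
]

LABEL_DECREASED = "decreased"
LABEL_INCREASED = "increased"
LABEL_NOT_SIGNIFICANT = "not_significant"
LABEL_NOT_TESTED = "not_tested"


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and knobs of the scoring scheme.

    ``fc_lower`` defaults to 1/1.5 — the symmetric counterpart of the >1.5
    upper gate.  ``ratio_scale`` selects whether the one-sample t-test is run
    on the raw MUT/WT ratios against 1 (default) or on log2 ratios against 0.
    """

    bait_id: str = "POLR1C"
    hci_ratio_threshold: float = 5.0
    noise_quantile: float = 0.20
    n_required_replicates: int = 3
    alpha: float = 0.05
    fc_upper: float = 1.5
    fc_lower: float = 1.0 / 1.5
    display_cap: float = -4.5
    ratio_scale: str = "raw"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.noise_quantile < 1:
            raise ValidationError("noise_quantile must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.fc_lower < 1 < self.fc_upper:
            raise ValidationError("need 0 < fc_lower < 1 < fc_upper")
        if self.hci_ratio_threshold <= 0:
            raise ValidationError("hci_ratio_threshold must be positive")
        if self.ratio_scale not in ("raw", "log2"):
            raise ValidationError("ratio_scale must be 'raw' or 'log2'")
        if self.n_required_replicates < 2:
            raise ValidationError("n_required_replicates must be >= 2")


@dataclass
class InteractorSummary:
    protein_id: str
    mean_wt: float
    mean_mut: float
    mean_ev: float
    ratio_wt_ev: float
    ratio_mut_ev: float
    high_confidence: bool
    basis: str | None  # "WT" | "MUT" | "both" | None


@dataclass
class DifferentialResult:
    protein_id: str
    ratios: tuple[float, ...]
    mean_ratio: float
    log2_mean_ratio: float
    t_statistic: float
    degrees_of_freedom: int
    p_raw: float
    p_adjusted: float | None = None
    label: str | None = None
    basis: str | None = None


# ---------------------------------------------------------------------------
# Normalization and imputation


def analysis_universe(raw: SpectralCountTable, runs: list[str] | None = None) -> list[str]:
    """Proteins observed (count > 0) in at least one of the given runs.

    This is the set over which zeros are imputed and tests are considered:
    proteins never identified in any run of the comparison do not exist for
    the analysis.
    """
    df = raw.data
    if runs is not None:
        df = df[df["run_id"].isin(runs)]
    return sorted(df.loc[df["count"] > 0, "protein_id"].unique())


def normalize_by_bait(table: SpectralCountTable, bait_id: str) -> SpectralCountTable:
    """Divide every count by its run's bait count (bait becomes exactly 1).

    Raises :class:`NormalizationError`, naming the run, if the bait is absent
    or zero in any run of the table.
    """
    df = table.data
    bait = df[df["protein_id"] == bait_id].set_index("run_id")["count"]
    for run in table.runs:
        if run not in bait.index or bait[run] <= 0:
            raise NormalizationError(
                f"bait {bait_id!r} absent or zero in run {run!r}; cannot normalize"
            )
    out = df.copy()
    out["count"] = out["count"].astype(float) / out["run_id"].map(bait).astype(float)
    return SpectralCountTable(data=out, kind=NORMALIZED)


def _noise_floor_params(nonzero: np.ndarray, quantile: float) -> tuple[float, float]:
    """Mean and (n-1) s.d. of the lowest ``ceil(quantile*m)`` nonzero counts."""
    m = nonzero.size
    k = math.ceil(quantile * m)
    s = np.sort(nonzero)[:k]
    mu = float(np.mean(s))
    sd = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    return mu, sd


def impute_zero_counts(
    table: SpectralCountTable,
    config: ScoringConfig,
    rng: np.random.Generator,
    universe: list[str] | None = None,
    runs: list[str] | None = None,
) -> SpectralCountTable:
    """Replace zero counts with per-run background-noise draws.

    For each run independently, the noise floor is Normal(mean, sd) of the
    lowest ``noise_quantile`` fraction of the run's nonzero counts; every
    zero — explicit, or implicit for a protein of the analysis universe not
    listed in the run — becomes an independent draw from that distribution,
    truncated below at ``max(0.01, mean - 3*sd)`` so imputed counts stay
    positive.  Nonzero counts are untouched.  Deterministic given the rng
    state: runs are processed in sorted order, proteins in sorted order.
    """
    if universe is None:
        universe = analysis_universe(table, runs)
    run_ids = sorted(runs) if runs is not None else table.runs
    mat = table.matrix(runs=run_ids).reindex(
        index=universe, columns=run_ids, fill_value=0.0
    )
    values = mat.to_numpy(dtype=float, copy=True)
    for j, run in enumerate(run_ids):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size < 2:
            raise ImputationError(
                f"run {run!r} has {nonzero.size} nonzero counts; "
                "need >= 2 to define the noise distribution"
            )
        mu, sd = _noise_floor_params(nonzero, config.noise_quantile)
        floor = max(0.01, mu - 3.0 * sd)
        zeros = np.flatnonzero(col == 0)
        if zeros.size:
            draws = rng.normal(mu, sd, size=zeros.size)
            col[zeros] = np.maximum(draws, floor)
    long = (
        pd.DataFrame(values, index=mat.index, columns=mat.columns)
        .rename_axis("protein_id")
        .reset_index()
        .melt(id_vars="protein_id", var_name="run_id", value_name="count")
    )
    return SpectralCountTable(data=long, kind=IMPUTED)


# ---------------------------------------------------------------------------
# High-confidence interactor filter


def _arm_runs(design: RunDesign, variant: str, config: ScoringConfig):
    wt = design.runs_for("WT")
    mut = design.runs_for(f"MUT:{variant}")
    ev = design.runs_for("EV")
    n = config.n_required_replicates
    if len(ev) < n:
        raise DesignError(f"need >= {n} EV runs, found {len(ev)}")
    if len(wt) < n or len(mut) < n:
        raise DesignError(
            f"need >= {n} WT and MUT:{variant} runs, found {len(wt)} and {len(mut)}"
        )
    return wt, mut, ev


def flag_high_confidence(
    raw: SpectralCountTable,
    counts: SpectralCountTable,
    design: RunDesign,
    variant: str,
    config: ScoringConfig,
) -> list[InteractorSummary]:
    """Apply the high-confidence interactor filter.

    A protein qualifies through an arm (WT or MUT) when its *raw* count is
    nonzero in every replicate of that arm AND the mean of its ``counts``
    entries over the arm exceeds the EV mean by strictly more than
    ``hci_ratio_threshold``-fold.  ``counts`` is typically the zero-imputed
    table on the raw spectral-count scale, so EV means are finite and
    comparable to the arms.  Summaries are returned for every protein of the
    ``counts`` universe, flagged or not.
    """
    wt_runs, mut_runs, ev_runs = _arm_runs(design, variant, config)
    mat = counts.matrix()
    raw_mat = raw.matrix().reindex(
        index=mat.index, columns=wt_runs + mut_runs, fill_value=0.0
    )
    thr = config.hci_ratio_threshold

    def _means(runs: list[str]) -> np.ndarray:
        return (
            mat.reindex(columns=runs).fillna(0.0).mean(axis=1).to_numpy(dtype=float)
        )

    mean_wt, mean_mut, mean_ev = _means(wt_runs), _means(mut_runs), _means(ev_runs)
    with np.errstate(divide="ignore"):
        ratio_wt = np.where(mean_ev > 0, mean_wt / np.where(mean_ev > 0, mean_ev, 1), np.inf)
        ratio_mut = np.where(mean_ev > 0, mean_mut / np.where(mean_ev > 0, mean_ev, 1), np.inf)
    present_wt = (raw_mat[wt_runs] > 0).all(axis=1).to_numpy()
    present_mut = (raw_mat[mut_runs] > 0).all(axis=1).to_numpy()
    wt_ok = present_wt & (ratio_wt > thr)
    mut_ok = present_mut & (ratio_mut > thr)
    out: list[InteractorSummary] = []
    for i, protein in enumerate(mat.index):
        basis = (
            "both"
            if (wt_ok[i] and mut_ok[i])
            else "WT" if wt_ok[i] else "MUT" if mut_ok[i] else None
        )
        out.append(
            InteractorSummary(
                protein_id=str(protein),
                mean_wt=float(mean_wt[i]),
                mean_mut=float(mean_mut[i]),
                mean_ev=float(mean_ev[i]),
                ratio_wt_ev=float(ratio_wt[i]),
                ratio_mut_ev=float(ratio_mut[i]),
                high_confidence=basis is not None,
                basis=basis,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Differential testing


def _one_sample_t(x: np.ndarray, null: float) -> tuple[float, float]:
    """Two-tailed one-sample t of mean(x) against ``null``.

    A zero-variance series sitting exactly at the null is maximally
    uninformative (p = 1); a zero-variance series away from the null is
    infinitely significant (p = 0).
    """
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        if mean == null:
            return 0.0, 1.0
        return math.copysign(math.inf, mean - null), 0.0
    t = (mean - null) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, min(p, 1.0)


def differential_interaction_test(
    normalized: SpectralCountTable,
    design: RunDesign,
    variant: str,
    proteins: list[str],
    config: ScoringConfig,
) -> list[DifferentialResult]:
    """Paired MUT/WT ratio t-tests for the given proteins.

    Per protein, one ratio per WT↔MUT pair from the bait-normalized, imputed
    table.  ``ratio_scale='raw'`` tests mean(r) against 1; ``'log2'`` tests
    mean(log2 r) against 0.  ``mean_ratio`` is always the arithmetic mean of
    the raw ratios (the quantity displayed as fold change).
    """
    pairs = design.pairs(variant)
    if len(pairs) < 2:
        raise TestError(f"variant {variant!r} has {len(pairs)} pairs; need >= 2")
    mat = normalized.matrix()
    results = []
    for protein in proteins:
        if protein not in mat.index:
            raise TestError(f"protein {protein!r} missing from normalized table")
        row = mat.loc[protein]
        num = row.reindex([m for _, m in pairs]).to_numpy(dtype=float)
        den = row.reindex([w for w, _ in pairs]).to_numpy(dtype=float)
        if np.any(den <= 0) or np.any(num <= 0):
            raise TestError(
                f"protein {protein!r} has non-positive counts in a pair; "
                "impute zeros before testing"
            )
        r = num / den
        mean_ratio = float(np.mean(r))
        if config.ratio_scale == "raw":
            t, p = _one_sample_t(r, 1.0)
        else:
            t, p = _one_sample_t(np.log2(r), 0.0)
        results.append(
            DifferentialResult(
                protein_id=protein,
                ratios=tuple(float(v) for v in r),
                mean_ratio=mean_ratio,
                log2_mean_ratio=float(np.log2(mean_ratio)),
                t_statistic=t,
                degrees_of_freedom=len(pairs) - 1,
                p_raw=p,
            )
        )
    return results


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_interactions(
    results: list[DifferentialResult], config: ScoringConfig
) -> list[DifferentialResult]:
    """Attach the dual-criterion significance label to each tested result."""
    out = []
    for res in results:
        if res.p_adjusted is None:
            raise ValidationError(f"protein {res.protein_id!r} has no adjusted p")
        if res.p_adjusted < config.alpha and res.mean_ratio < config.fc_lower:
            label = LABEL_DECREASED
        elif res.p_adjusted < config.alpha and res.mean_ratio > config.fc_upper:
            label = LABEL_INCREASED
        else:
            label = LABEL_NOT_SIGNIFICANT
        out.append(replace(res, label=label))
    return out


def build_display_matrix(
    results_by_variant: dict[str, list[DifferentialResult]],
    config: ScoringConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heatmap matrix (protein x variant capped log2 ratios) + volcano table.

    log2 mean ratios below ``display_cap`` are shown as the cap; the volcano
    table carries one row per (variant, protein) with the signed log2 ratio,
    ``-log10`` adjusted p, the label and a significance flag for colouring.
    """
    heat: dict[str, pd.Series] = {}
    volcano_rows = []
    for variant, results in results_by_variant.items():
        col = {}
        for res in results:
            capped = max(res.log2_mean_ratio, config.display_cap)
            col[res.protein_id] = capped
            if res.p_adjusted is None or res.label is None:
                raise ValidationError("classify results before building displays")
            neglog = (
                math.inf if res.p_adjusted == 0 else -math.log10(res.p_adjusted)
            )
            volcano_rows.append(
                {
                    "variant": variant,
                    "protein_id": res.protein_id,
                    "log2_mean_ratio": res.log2_mean_ratio,
                    "neg_log10_p_adjusted": neglog,
                    "label": res.label,
                    "significant": res.label in (LABEL_DECREASED, LABEL_INCREASED),
                }
            )
        heat[variant] = pd.Series(col)
    heatmap = pd.DataFrame(heat).rename_axis("protein_id").sort_index()
    volcano = pd.DataFrame(
        volcano_rows,
        columns=[
            "variant",
            "protein_id",
            "log2_mean_ratio",
            "neg_log10_p_adjusted",
            "label",
            "significant",
        ],
    )
    return heatmap, volcano


# ---------------------------------------------------------------------------
# End-to-end convenience


def analyze_variant(
    raw: SpectralCountTable,
    design: RunDesign,
    variant: str,
    config: ScoringConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[InteractorSummary], list[DifferentialResult]]:
    """Full scoring of one mutant-vs-WT comparison.

    impute (raw scale, per run, over the WT/MUT/EV universe) → normalize the
    bait-containing runs by the bait → flag high-confidence interactors
    (presence on raw counts; EV ratio on imputed raw-scale counts) → paired
    t-tests on normalized ratios → BH adjustment over this comparison's
    high-confidence family → dual-criterion labels.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    wt_runs, mut_runs, ev_runs = _arm_runs(design, variant, config)
    trio = wt_runs + mut_runs + ev_runs
    universe = analysis_universe(raw, trio)
    sub = raw.with_data(raw.data[raw.data["run_id"].isin(trio)].reset_index(drop=True))
    imputed = impute_zero_counts(sub, config, rng, universe=universe, runs=trio)
    arm_only = imputed.with_data(
        imputed.data[imputed.data["run_id"].isin(wt_runs + mut_runs)].reset_index(
            drop=True
        )
    )
    normalized = normalize_by_bait(arm_only, config.bait_id)
    summaries = flag_high_confidence(sub, imputed, design, variant, config)
    hci = [s.protein_id for s in summaries if s.high_confidence]
    results = differential_interaction_test(normalized, design, variant, hci, config)
    adj = adjust_bh([r.p_raw for r in results])
    results = [replace(r, p_adjusted=float(a)) for r, a in zip(results, adj)]
    results = classify_interactions(results, config)
    basis = {s.protein_id: s.basis for s in summaries}
    results = [replace(r, basis=basis[r.protein_id]) for r in results]
    return summaries, results
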