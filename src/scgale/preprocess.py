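"""Quantile-based QC, library-size normalisation, variable-feature selection,
log transform, and the Wilcoxon one-vs-rest differential baseline.

Conventions (documented rather than silently assumed):

* quantiles use linear interpolation between order statistics, and a cell or
  feature is removed only when *strictly* outside the [5%, 95%] band — a
  degenerate all-equal distribution therefore removes nothing;
* the per-gene filter operates on detection counts (number of cells with a
  non-zero value), computed on the cells that survived the cell rules;
* variance for feature selection is taken on normalised, pre-log values;
  ties are broken by ascending feature index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, QCReport

TSS_MIN = 2.0
NUCLEOSOME_MAX = 2.0


def _quantile_band(values: np.ndarray, lo: float = 0.05, hi: float = 0.95):
    return float(np.quantile(values, lo)), float(np.quantile(values, hi))


def _outside(values: np.ndarray, q_lo: float, q_hi: float) -> np.ndarray:
    return (values < q_lo) | (values > q_hi)


def compute_mito_counts(m: CountMatrix, prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell mitochondrial read counts from feature-id prefix matching."""
    mito = np.array([str(f).startswith(prefix) for f in m.feature_ids])
    counts = m.counts[:, mito].sum(axis=1)
    qc = m.qc.copy() if m.qc is not None else pd.DataFrame(index=range(m.n_cells))
    qc["mito_count"] = counts
    return qc


def _feature_detection_filter(m: CountMatrix, thresholds: dict, removals: dict):
    detection = (m.counts > 0).sum(axis=0)
    q_lo, q_hi = _quantile_band(detection)
    drop = _outside(detection, q_lo, q_hi)
    thresholds["feature_detection_q5"] = q_lo
    thresholds["feature_detection_q95"] = q_hi
    removals["features_outside_detection_band"] = int(drop.sum())
    return m.subset_features(np.flatnonzero(~drop))


def qc_filter_gex(m: CountMatrix) -> Tuple[CountMatrix, QCReport]:
    """Quantile QC for gene-expression matrices.

    Removes cells whose non-zero-gene count or mitochondrial read count lies
    strictly outside the [5%, 95%] quantiles of the respective per-cell
    distributions, then genes whose detection count lies strictly outside the
    same band of the per-gene distribution. A missing ``mito_count`` column
    skips the mitochondrial rule (recorded, not fatal).
    """
    if m.modality != "GEX":
        raise ValueError("qc_filter_gex expects a GEX matrix")
    if m.is_normalised:
        raise ValueError("QC must run on raw counts")
    thresholds: dict = {}
    removals: dict = {}
    skipped: List[str] = []

    nz = (m.counts > 0).sum(axis=1)
    q_lo, q_hi = _quantile_band(nz)
    drop_cells = _outside(nz, q_lo, q_hi)
    thresholds["nonzero_genes_q5"], thresholds["nonzero_genes_q95"] = q_lo, q_hi
    removals["cells_outside_nonzero_gene_band"] = int(drop_cells.sum())
    # cells detecting nothing are unusable regardless of the band
    removals["cells_with_no_detected_features"] = int((nz == 0).sum())
    drop_cells |= nz == 0

    if m.qc is not None and "mito_count" in m.qc.columns:
        mito = np.asarray(m.qc["mito_count"], dtype=float)
        mq_lo, mq_hi = _quantile_band(mito)
        mito_drop = _outside(mito, mq_lo, mq_hi)
        thresholds["mito_count_q5"], thresholds["mito_count_q95"] = mq_lo, mq_hi
        removals["cells_outside_mito_band"] = int((mito_drop & ~drop_cells).sum())
        drop_cells |= mito_drop
    else:
        skipped.append("mito_count")

    kept = np.flatnonzero(~drop_cells)
    if len(kept) == 0:
        raise ValueError("QC removed every cell")
    out = m.subset_cells(kept)
    out = _feature_detection_filter(out, thresholds, removals)
    if out.n_features == 0:
        raise ValueError("QC removed every feature")
    report = QCReport(
        n_cells_in=m.n_cells, n_cells_out=out.n_cells,
        n_features_in=m.n_features, n_features_out=out.n_features,
        thresholds=thresholds, removals=removals, skipped_rules=skipped,
    )
    return out, report


def qc_filter_peaks(m: CountMatrix) -> Tuple[CountMatrix, QCReport]:
    """Quantile + signal QC for peak/window matrices.

    Cell rules: feature count strictly outside [5%, 95%]; TSS enrichment
    below 2; nucleosome signal above 2 (signal rules apply only when the
    columns are present). Feature rule: detection band as in the GEX filter.
    """
    if m.modality not in ("PEAKS", "WINDOWS"):
        raise ValueError("qc_filter_peaks expects a PEAKS or WINDOWS matrix")
    if m.is_normalised:
        raise ValueError("QC must run on raw counts")
    thresholds: dict = {}
    removals: dict = {}
    skipped: List[str] = []

    nz = (m.counts > 0).sum(axis=1)
    q_lo, q_hi = _quantile_band(nz)
    drop_cells = _outside(nz, q_lo, q_hi)
    thresholds["feature_count_q5"], thresholds["feature_count_q95"] = q_lo, q_hi
    removals["cells_outside_feature_count_band"] = int(drop_cells.sum())
    removals["cells_with_no_detected_features"] = int((nz == 0).sum())
    drop_cells |= nz == 0

    for col, rule in (("tss_enrichment", "tss"), ("nucleosome_signal", "nucleosome")):
        if m.qc is not None and col in m.qc.columns:
            vals = np.asarray(m.qc[col], dtype=float)
            bad = vals < TSS_MIN if rule == "tss" else vals > NUCLEOSOME_MAX
            thresholds[f"{col}_cutoff"] = TSS_MIN if rule == "tss" else NUCLEOSOME_MAX
            removals[f"cells_failing_{rule}"] = int((bad & ~drop_cells).sum())
            drop_cells |= bad
        else:
            skipped.append(col)

    kept = np.flatnonzero(~drop_cells)
    if len(kept) == 0:
        raise ValueError("QC removed every cell")
    out = m.subset_cells(kept)
    out = _feature_detection_filter(out, thresholds, removals)
    if out.n_features == 0:
        raise ValueError("QC removed every feature")
    report = QCReport(
        n_cells_in=m.n_cells, n_cells_out=out.n_cells,
        n_features_in=m.n_features, n_features_out=out.n_features,
        thresholds=thresholds, removals=removals, skipped_rules=skipped,
    )
    return out, report


def normalize_library_size(m: CountMatrix, target_sum="median") -> CountMatrix:
    """Scale each cell so its total count equals ``target_sum``.

    The default target is the median of per-cell totals. Cells with a zero
    total are rejected (run QC first).
    """
    if m.is_normalised:
        raise ValueError("matrix is already normalised")
    totals = m.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(
            f"{int((totals == 0).sum())} cells have zero total counts; "
            "apply QC filtering before normalisation"
        )
    target = float(np.median(totals)) if target_sum == "median" else float(target_sum)
    if target <= 0:
        raise ValueError("target_sum must be positive")
    out = m.copy()
    out.counts = m.counts * (target / totals)[:, None]
    out.is_normalised = True
    return out


def _variances(m: CountMatrix) -> np.ndarray:
    return m.counts.var(axis=0)


def select_hvg_gex(m: CountMatrix, top_frac: float = 0.10) -> CountMatrix:
    """Keep the ⌈top_frac·F⌉ highest-variance genes (normalised, pre-log)."""
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    if not m.is_normalised:
        raise ValueError("select features after normalisation")
    if m.is_log:
        raise ValueError("select features before the log transform")
    k = int(np.ceil(top_frac * m.n_features))
    var = _variances(m)
    order = np.argsort(-var, kind="stable")[:k]  # ties → ascending index
    return m.subset_features(np.sort(order))


def select_hv_peaks(
    m: CountMatrix, var_quantile: float = 0.80, max_features: int = 30000
) -> CountMatrix:
    """Keep features with variance strictly above the ``var_quantile``
    quantile, truncated to the ``max_features`` highest-variance ones."""
    if not 0 < var_quantile < 1:
        raise ValueError("var_quantile must be in (0, 1)")
    if not m.is_normalised:
        raise ValueError("select features after normalisation")
    if m.is_log:
        raise ValueError("select features before the log transform")
    var = _variances(m)
    cut = np.quantile(var, var_quantile)
    passing = np.flatnonzero(var > cut)
    if len(passing) == 0:
        raise ValueError(
            "no feature variance strictly above the quantile cut; "
            "lower var_quantile"
        )
    if len(passing) > max_features:
        order = np.argsort(-var[passing], kind="stable")[:max_features]
        passing = passing[order]
    return m.subset_features(np.sort(passing))


def log_transform(m: CountMatrix) -> CountMatrix:
    """Entrywise natural log(1 + x)."""
    if m.is_log:
        raise ValueError("matrix is already log-transformed")
    if not m.is_normalised:
        raise ValueError("log-transform after normalisation")
    out = m.copy()
    out.counts = np.log1p(m.counts)
    out.is_log = True
    return out


# ---------------------------------------------------------------------------
# Wilcoxon one-vs-rest differential analysis
# ---------------------------------------------------------------------------

@dataclass
class DAResult:
    """Per-class ranked feature tables from the Wilcoxon rank-sum baseline."""

    tables: Dict[str, pd.DataFrame]
    n_top: int

    def top_sets(self, n: int | None = None) -> Dict[str, List[str]]:
        n = self.n_top if n is None else n
        return {c: list(t["feature_id"].iloc[:n]) for c, t in self.tables.items()}


def _exact_pvalues(ranks: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Exact two-sided rank-sum p per feature by enumerating all assignments."""
    n, F = ranks.shape
    n1 = int(in_mask.sum())
    combos = np.array(list(itertools.combinations(range(n), n1)))
    # rank-sum distribution per feature: (n_combos, F)
    sums = ranks[combos].sum(axis=1)
    obs = ranks[in_mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    dev = np.abs(obs - mu)
    return (np.abs(sums - mu) >= dev - 1e-12).mean(axis=0)


def wilcoxon_da(m: CountMatrix, n_top: int = 50, exact_max_n: int = 20) -> DAResult:
    """One-vs-rest two-sided Wilcoxon rank-sum per feature and class.

    Features are ranked per class by the standardised rank-sum statistic,
    descending (most up-regulated first), midranks for ties; p-values use
    the tie-corrected normal approximation, or exact enumeration when the
    comparison involves at most ``exact_max_n`` cells in total.
    """
    if not m.is_log:
        raise ValueError("wilcoxon_da expects a log-transformed matrix")
    if m.labels is None:
        raise ValueError("wilcoxon_da requires labels")
    cats, codes = m.label_codes()
    if len(cats) < 2:
        raise ValueError("need at least 2 classes")
    for c, cat in enumerate(cats):
        if (codes == c).sum() < 2:
            raise ValueError(f"class {cat!r} has fewer than 2 cells")

    X = m.counts
    n, F = X.shape
    ranks = rankdata(X, axis=0)  # midranks
    # tie correction term per feature
    tie_term = np.zeros(F)
    for j in range(F):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = ((cnt ** 3 - cnt).sum()) / (n * (n - 1.0))

    tables: Dict[str, pd.DataFrame] = {}
    for c, cat in enumerate(cats):
        mask = codes == c
        n1 = int(mask.sum())
        n2 = n - n1
        r1 = ranks[mask].sum(axis=0)
        mu = n1 * (n + 1) / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sigma > 0, (r1 - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
        if n <= exact_max_n:
            pvals = _exact_pvalues(ranks, mask)
        else:
            from scipy.stats import norm

            pvals = np.where(sigma > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
        order = np.lexsort((np.arange(F), -z))
        tables[str(cat)] = pd.DataFrame(
            {
                "feature_id": np.asarray(m.feature_ids)[order].astype(str),
                "statistic": z[order],
                "pvalue": pvals[order],
            }
        ).reset_index(drop=True)
    return DAResult(tables=tables, n_top=n_top)
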