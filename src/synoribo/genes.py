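"""Gene-level analyses: mutation-density enrichment by gene class,
translation efficiency, and the TE fold-change regression.

SNP density is the number of tumor-specific synonymous mutations of a given
optimality class per kb of CDS.  Translation efficiency (TE) is
RPKM_RPF / RPKM_mRNA per gene per sample; the fold change tumor/normal is
regressed (ordinary least squares) on mutation counts and nuisance
covariates, every predictor min-max scaled to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

GENE_CLASSES = ("oncogene", "TSG", "other")

DEFAULT_PREDICTORS = (
    "n_optimal_syn",
    "n_nonoptimal_syn",
    "gene_length",
    "dn",
    "expression",
    "gc_content",
)


def snp_density(count: int, cds_len: int) -> float:
    """Mutations per kb of CDS: ``1000 * count / cds_len``."""
    if cds_len <= 0:
        raise ValueError("cds_len must be > 0")
    return 1000.0 * count / cds_len


def gene_mutation_counts(
    merged_variants: pd.DataFrame,
    cds_models: pd.DataFrame,
    consequence: str = "synonymous",
) -> pd.DataFrame:
    """Per-gene counts of (unique, merged-across-patients) synonymous
    variants by optimality class, with densities per kb CDS."""
    cds_len = (cds_models["cds_end"] - cds_models["cds_start"]).rename("cds_len")
    out = pd.DataFrame({"gene": cds_models["gene"], "cds_len": cds_len})
    sub = merged_variants[merged_variants["consequence"] == consequence]
    for klass, col in (("optimal", "n_optimal_syn"), ("non_optimal", "n_nonoptimal_syn")):
        counts = (
            sub[sub["optimality"] == klass].groupby("gene").size().rename(col)
        )
        out = out.merge(counts, on="gene", how="left")
        out[col] = out[col].fillna(0).astype(int)
    out["snp_density_opt"] = 1000.0 * out["n_optimal_syn"] / out["cds_len"]
    out["snp_density_nonopt"] = 1000.0 * out["n_nonoptimal_syn"] / out["cds_len"]
    return out


@dataclass
class EnrichmentResult:
    """KS comparisons of SNP densities between gene classes."""

    comparisons: dict[str, dict] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"comparison": k, **v} for k, v in self.comparisons.items()]
        )


def class_enrichment(summaries: pd.DataFrame) -> EnrichmentResult:
    """Compare per-gene SNP densities across gene classes.

    Three comparisons: optimal density in oncogenes vs TSG, non-optimal
    density in oncogenes vs TSG, and optimal vs non-optimal density within
    the remaining genes.  Two-sided two-sample KS tests; directions are the
    sign of the mean difference.
    """
    by = {k: summaries[summaries["class"] == k] for k in GENE_CLASSES}
    if by["oncogene"].empty or by["TSG"].empty:
        raise ValueError("insufficient data: need populated oncogene and TSG classes")
    res = EnrichmentResult()

    def ks(x, y):
        r = stats.ks_2samp(np.asarray(x, float), np.asarray(y, float))
        return float(r.statistic), float(r.pvalue)

    for label, col in (
        ("optimal_onco_vs_tsg", "snp_density_opt"),
        ("nonoptimal_onco_vs_tsg", "snp_density_nonopt"),
    ):
        s, p = ks(by["oncogene"][col], by["TSG"][col])
        res.comparisons[label] = {
            "statistic": s,
            "p_value": p,
            "mean_oncogene": float(by["oncogene"][col].mean()),
            "mean_tsg": float(by["TSG"][col].mean()),
            "direction": "oncogene>TSG"
            if by["oncogene"][col].mean() > by["TSG"][col].mean()
            else "TSG>oncogene",
        }
    other = by["other"]
    if len(other):
        s, p = ks(other["snp_density_opt"], other["snp_density_nonopt"])
        res.comparisons["other_opt_vs_nonopt"] = {
            "statistic": s,
            "p_value": p,
            "mean_oncogene": float("nan"),
            "mean_tsg": float("nan"),
            "direction": "optimal>non_optimal"
            if other["snp_density_opt"].mean() > other["snp_density_nonopt"].mean()
            else "non_optimal>optimal",
        }
    return res


def top_genes(
    summaries: pd.DataFrame,
    gene_class: str,
    optimality: str,
    k: int = 10,
) -> pd.DataFrame:
    """Genes of one class ranked by the requested SNP density, descending.

    Ties are broken by raw mutation count (higher first), then gene id.
    Returns at most ``k`` rows with density and count ("Freq").
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dcol = "snp_density_opt" if optimality == "optimal" else "snp_density_nonopt"
    ccol = "n_optimal_syn" if optimality == "optimal" else "n_nonoptimal_syn"
    sub = summaries[summaries["class"] == gene_class].copy()
    sub = sub.sort_values(
        [dcol, ccol, "gene"], ascending=[False, False, True]
    ).head(k)
    return sub[["gene", "class", dcol, ccol]].rename(
        columns={dcol: "snp_density", ccol: "freq"}
    ).reset_index(drop=True)


def rpkm(counts: np.ndarray | pd.Series, lengths_nt, library_size: float):
    """Reads per kilobase per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    return 1e9 * counts / (np.asarray(lengths_nt, dtype=float) * library_size)


def translation_efficiency(
    rna_counts,
    rpf_counts,
    lengths_nt,
    rna_library_size: float,
    rpf_library_size: float,
):
    """TE per gene: RPKM_RPF / RPKM_mRNA; undefined (NaN) where mRNA RPKM is 0."""
    r_rna = rpkm(rna_counts, lengths_nt, rna_library_size)
    r_rpf = rpkm(rpf_counts, lengths_nt, rpf_library_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(r_rna > 0, r_rpf / r_rna, np.nan)
    return te


def minmax_scale_signed(x: np.ndarray) -> np.ndarray:
    """Min-max scale to [-1, 1]: ``2 (x - min) / (max - min) - 1``."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return 2.0 * (x - x.min()) / span - 1.0


class TEFoldChangeRegression(BaseEstimator):
    """OLS of TE fold change on min-max-scaled predictors.

    sklearn-style estimator.  The response is log2(TE_tumor / TE_normal) by
    default (``log_response=False`` uses the raw ratio); every predictor is
    min-max scaled to [-1, 1] before an ordinary-least-squares fit with
    intercept.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_, bse_, pvalues_ : pandas.Series indexed by predictor name
    result_ : the statsmodels regression results object
    feature_names_in_ : list of predictor names
    """

    def __init__(self, predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
                 log_response: bool = True):
        self.predictors = predictors
        self.log_response = log_response

    def fit(self, X: pd.DataFrame, y: np.ndarray | pd.Series) -> "TEFoldChangeRegression":
        cols = [p for p in self.predictors if p in X.columns]
        missing = set(self.predictors) - set(cols)
        if missing:
            raise ValueError(f"missing predictors: {sorted(missing)}")
        y = np.asarray(y, dtype=float)
        design = np.column_stack(
            [minmax_scale_signed(X[c].to_numpy()) for c in cols]
        )
        keep = np.isfinite(y) & np.isfinite(design).all(axis=1)
        y, design = y[keep], design[keep]
        if len(y) < 10 * len(cols):
            raise ValueError(
                f"need >= {10 * len(cols)} complete genes, got {len(y)}"
            )
        exog = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            full_rank = np.linalg.matrix_rank(exog)
            collinear = [
                cols[i]
                for i in range(len(cols))
                if np.linalg.matrix_rank(np.delete(exog, i + 1, axis=1)) == full_rank
            ]
            raise ValueError(f"rank-deficient design; collinear predictors: {collinear}")
        res = sm.OLS(y, exog).fit()
        names = ["const", *cols]
        self.feature_names_in_ = cols
        self.coef_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.bse, index=names)
        self.pvalues_ = pd.Series(res.pvalues, index=names)
        self.result_ = res
        self.n_obs_ = int(len(y))
        return self

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef_, "se": self.bse_, "p_value": self.pvalues_}
        ).rename_axis("term")


def te_regression(
    summaries: pd.DataFrame,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    log_response: bool = True,
) -> TEFoldChangeRegression:
    """Fit the TE fold-change regression from a gene-summary table with
    ``te_normal``/``te_tumor`` columns and the predictor columns."""
    te_n = summaries["te_normal"].to_numpy(dtype=float)
    te_t = summaries["te_tumor"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((te_n > 0) & (te_t > 0), te_t / te_n, np.nan)
    y = np.log2(ratio) if log_response else ratio
    model = TEFoldChangeRegression(predictors=predictors, log_response=log_response)
    return model.fit(summaries, y)
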