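"""Transcriptome stage: RPKM normalization, background subtraction, three
differential-expression detection routes, their consensus, and sequencing QC
summary arithmetic.

The screen compares cells expressing a wild-type transcription factor with
cells expressing a truncated mutant, against non-transfected controls whose
reads are treated as shared background.  Three independent detection routes
are provided:

``route_subtractive``
    Student's t-test plus a minimum fold change on background-subtracted,
    RPKM-normalized replicate expression.
``detect_by_sigma``
    Thresholding of the mutant/wild-type log2 fold change at ``k`` times the
    s.d.-about-zero of the whole log2FC vector (k = 3 and k = 6 are the two
    conventional stringencies).
``route_count_test``
    A two-step negative-binomial count test (wild-type vs control first, then
    mutant vs wild-type on the survivors), an openly simplified stand-in for
    DESeq-style analysis: median-of-ratios size factors, method-of-moments
    pooled dispersion, and a Wald-type test with Benjamini-Hochberg control.

``consensus_hits`` intersects any number of routes requiring an identical
direction of change.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("control", "wildtype", "mutant")

UP = "up"
DOWN = "down"


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with gene lengths and sample labels.

    Parameters
    ----------
    counts
        DataFrame indexed by feature_id with one column per sample.
    lengths
        Series of transcript lengths in bp, indexed like ``counts``.
    samples
        DataFrame indexed by sample id with columns ``condition`` (one of
        ``control``/``wildtype``/``mutant``) and ``replicate``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise CountMatrixError("feature_ids are not unique")
        if not self.counts.index.equals(self.lengths.index):
            raise CountMatrixError("lengths index does not match counts index")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise CountMatrixError(f"non-positive length for feature {bad!r}")
        if (self.counts.to_numpy() < 0).any():
            raise CountMatrixError("negative counts present")
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise CountMatrixError(f"sample {bad!r} has zero total count")
        unknown = set(self.samples["condition"]) - set(CONDITIONS)
        if unknown:
            raise CountMatrixError(f"unknown condition labels: {sorted(unknown)}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise CountMatrixError(f"samples missing from sample sheet: {sorted(missing)}")

    def condition_columns(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise CountMatrixError(f"unknown condition {condition!r}")
        cols = [c for c in self.counts.columns if self.samples.loc[c, "condition"] == condition]
        return cols

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        """Read a counts TSV (``feature_id  length_bp  <samples>``) plus a
        sample sheet TSV (``sample_id  condition  replicate``)."""
        raw = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        lengths = raw.pop("length_bp")
        return cls(counts=raw, lengths=lengths, samples=samples)


@dataclass
class SigmaEstimate:
    """Root-mean-square of log2 fold changes about zero.

    ``sigma`` is the deviation of the log2FC vector from its assumed mean of
    0 ("no change"), which dominates the ordinary sample s.d. about the mean.
    ``sd_about_mean`` is reported alongside for transparency.
    """

    sigma: float
    n_valid: int
    sd_about_mean: float = field(default=float("nan"))

    def fold(self, k: int) -> float:
        return sigma_to_fold(self.sigma, k)


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM_gs = 1e9 * c_gs / (N_s * L_g) with N_s the per-sample total count.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    rpkm = 1e9 * cm.counts.div(totals, axis=1).div(cm.lengths, axis=0)
    return rpkm


def condition_means(expr: pd.DataFrame, cm: CountMatrix, condition: str) -> pd.Series:
    """Arithmetic mean of expression across a condition's replicates."""
    cols = cm.condition_columns(condition)
    if not cols:
        raise CountMatrixError(f"no samples with condition {condition!r}")
    return expr[cols].mean(axis=1)


def subtract_background(cond_mean: pd.Series, control_mean: pd.Series) -> pd.Series:
    """Subtract the normalized control (background) signal, clamping at 0."""
    if not cond_mean.index.equals(control_mean.index):
        raise ValueError("feature index mismatch between condition and control vectors")
    return (cond_mean - control_mean).clip(lower=0.0)


def compute_log2fc(
    mut_adj: pd.Series, wt_adj: pd.Series, pseudocount: float = 0.0
) -> tuple[pd.Series, pd.Series]:
    """Mutant-to-wild-type log2 fold change with a validity mask.

    A comparison is *valid* iff both adjusted values are > 0; log2FC is NaN
    for invalid features.  A pseudocount may be added for robustness studies.
    """
    if not mut_adj.index.equals(wt_adj.index):
        raise ValueError("feature index mismatch")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    valid = (mut_adj > 0) & (wt_adj > 0)
    lfc = pd.Series(np.nan, index=mut_adj.index)
    m = mut_adj[valid] + pseudocount
    w = wt_adj[valid] + pseudocount
    lfc[valid] = np.log2(m / w)
    return lfc, valid


def estimate_sigma_zero(log2fc: pd.Series | np.ndarray) -> SigmaEstimate:
    """s.d. of log2 fold changes as deviation from an assumed mean of zero.

    sigma = sqrt(mean(x_i^2)), the RMS about 0, not the sample s.d.  It
    always dominates the s.d. about the mean (equality iff the mean is 0).
    """
    x = np.asarray(pd.Series(log2fc).dropna(), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 valid log2FC values to estimate sigma")
    sigma = float(np.sqrt(np.mean(x**2)))
    return SigmaEstimate(sigma=sigma, n_valid=int(x.size), sd_about_mean=float(np.std(x)))


def sigma_to_fold(sigma: float, k: int) -> float:
    """Fold change corresponding to a k-sigma log2FC threshold: 2**(k*sigma)."""
    return float(2.0 ** (k * sigma))


def detect_by_sigma(log2fc: pd.Series, sigma: SigmaEstimate, k: int = 3) -> dict[str, str]:
    """Flag features whose |log2FC| strictly exceeds k*sigma.

    Returns a dict feature_id -> direction ('up'/'down').  Invalid (NaN)
    features are never flagged; ties at exactly k*sigma are not hits.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    thr = k * sigma.sigma
    hits: dict[str, str] = {}
    for fid, v in log2fc.items():
        if np.isnan(v):
            continue
        if v > thr:
            hits[fid] = UP
        elif v < -thr:
            hits[fid] = DOWN
    return hits


def route_subtractive(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
    min_fold: float = 1.5,
) -> dict[str, str]:
    """Background-subtraction route: t-test + fold filter on replicate RPKM.

    Per feature, each mutant and wild-type replicate's RPKM is reduced by the
    control condition mean (clamped at 0), log2-transformed with a small
    pseudocount, and compared by a two-sided two-sample Student's t-test.
    A hit requires p <= alpha and a mean fold change of at least ``min_fold``.
    """
    rpkm = compute_rpkm(cm)
    mut_cols = cm.condition_columns("mutant")
    wt_cols = cm.condition_columns("wildtype")
    if len(mut_cols) < 2 or len(wt_cols) < 2:
        raise ValueError("route_subtractive requires >=2 replicates per condition")
    ctl_mean = condition_means(rpkm, cm, "control")
    mut_adj = rpkm[mut_cols].sub(ctl_mean, axis=0).clip(lower=0.0)
    wt_adj = rpkm[wt_cols].sub(ctl_mean, axis=0).clip(lower=0.0)
    log_mut = np.log2(mut_adj + pseudocount)
    log_wt = np.log2(wt_adj + pseudocount)
    with warnings.catch_warnings():
        # near-constant rows trigger scipy's precision-loss warning; those
        # rows cannot reach significance anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(log_mut, log_wt, axis=1)
    diff = log_mut.mean(axis=1) - log_wt.mean(axis=1)
    min_abs_lfc = np.log2(min_fold)
    hit = (p <= alpha) & (np.abs(diff) >= min_abs_lfc)
    return {
        fid: (UP if d > 0 else DOWN)
        for fid, d, h in zip(cm.counts.index, diff, hit)
        if h and not np.isnan(d)
    }


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Genes with any zero count are excluded from the reference (their log
    geometric mean is -inf), the standard convention.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna() & np.isfinite(log_ref)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample; cannot compute size factors")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def _nb_wald_test(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, sf_a: pd.Series, sf_b: pd.Series
) -> pd.DataFrame:
    """Per-gene Wald-type NB test of condition b vs condition a.

    Normalized counts are treated as NB with a per-gene dispersion pooled by
    method of moments across the two conditions; the test statistic is the
    log2 fold change of condition means over its delta-method standard
    error, referred to a t distribution with the pooled degrees of freedom
    (the dispersion is itself estimated, so the normal reference is
    anti-conservative at these replicate numbers).
    """
    norm_a = counts_a.div(sf_a, axis=1)
    norm_b = counts_b.div(sf_b, axis=1)
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]

    def mom_dispersion(norm: pd.DataFrame, mu: pd.Series) -> pd.Series:
        var = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (var - mu) / mu**2
        return d.clip(lower=0.0).fillna(0.0)

    disp = ((n_a - 1) * mom_dispersion(norm_a, mu_a) + (n_b - 1) * mom_dispersion(norm_b, mu_b)) / (
        n_a + n_b - 2
    )
    # pseudo-mean of 0.5 keeps the statistic finite for all-zero conditions
    pc = 0.5
    lfc = np.log2((mu_b + pc) / (mu_a + pc))
    var_mean_a = (mu_a + disp * mu_a**2) / n_a
    var_mean_b = (mu_b + disp * mu_b**2) / n_b
    ln2 = np.log(2.0)
    se = np.sqrt(var_mean_a / (mu_a + pc) ** 2 + var_mean_b / (mu_b + pc) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * stats.t.sf(np.abs(z.fillna(0.0)), df=n_a + n_b - 2)
    return pd.DataFrame({"log2fc": lfc, "p": p}, index=counts_a.index)


def route_count_test(
    cm: CountMatrix,
    fdr_alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> dict[str, str]:
    """Two-step count-based route on raw reads.

    Step 1 screens wild-type against control, keeping genes expressed at
    least ``min_abs_log2fc`` log2 units above background at BH q < fdr_alpha.
    Step 2 tests mutant against wild-type restricted to the step-1 survivors,
    again at BH q < fdr_alpha.  Genes with all-zero counts are excluded.
    """
    ctl = cm.condition_columns("control")
    wt = cm.condition_columns("wildtype")
    mut = cm.condition_columns("mutant")
    if min(len(ctl), len(wt), len(mut)) < 2:
        raise ValueError("route_count_test requires >=2 replicates per condition")
    expressed = cm.counts.sum(axis=1) > 0
    counts = cm.counts.loc[expressed]
    sf = size_factors(counts)

    step1 = _nb_wald_test(counts[ctl], counts[wt], sf[ctl], sf[wt])
    q1 = pd.Series(multipletests(step1["p"], method="fdr_bh")[1], index=step1.index)
    survivors = step1.index[(q1 < fdr_alpha) & (step1["log2fc"] >= min_abs_log2fc)]
    if len(survivors) == 0:
        return {}

    step2 = _nb_wald_test(
        counts.loc[survivors, wt], counts.loc[survivors, mut], sf[wt], sf[mut]
    )
    q2 = pd.Series(multipletests(step2["p"], method="fdr_bh")[1], index=step2.index)
    hits = step2.index[q2 < fdr_alpha]
    return {fid: (UP if step2.loc[fid, "log2fc"] > 0 else DOWN) for fid in hits}


def consensus_hits(route_results: dict[str, dict[str, str]]) -> dict[str, str]:
    """Features flagged by every route with an identical direction."""
    if not route_results:
        raise ValueError("at least one route result is required")
    its = list(route_results.values())
    common = set(its[0])
    for h in its[1:]:
        common &= set(h)
    out = {}
    for fid in common:
        dirs = {h[fid] for h in its}
        if len(dirs) == 1:
            out[fid] = dirs.pop()
    return out


def run_de_pipeline(
    cm: CountMatrix,
    k_values: tuple[int, ...] = (3, 6),
    pseudocount: float = 0.0,
    subtractive_pseudocount: float = 0.5,
    alpha: float = 0.05,
    min_fold: float = 1.5,
    fdr_alpha: float = 0.05,
    consensus_routes: tuple[str, ...] = ("subtractive", "sigma_k3", "count_test"),
) -> pd.DataFrame:
    """Run all detection routes and assemble a per-feature result table.

    Returns a DataFrame with log2fc, validity, one direction column per
    route (``none`` when unflagged), and the consensus flag over
    ``consensus_routes``.
    """
    rpkm = compute_rpkm(cm)
    ctl_mean = condition_means(rpkm, cm, "control")
    wt_adj = subtract_background(condition_means(rpkm, cm, "wildtype"), ctl_mean)
    mut_adj = subtract_background(condition_means(rpkm, cm, "mutant"), ctl_mean)
    lfc, valid = compute_log2fc(mut_adj, wt_adj, pseudocount=pseudocount)
    sigma = estimate_sigma_zero(lfc)

    routes: dict[str, dict[str, str]] = {}
    for k in k_values:
        routes[f"sigma_k{k}"] = detect_by_sigma(lfc, sigma, k=k)
    routes["subtractive"] = route_subtractive(
        cm, pseudocount=subtractive_pseudocount, alpha=alpha, min_fold=min_fold
    )
    routes["count_test"] = route_count_test(cm, fdr_alpha=fdr_alpha)

    consensus = consensus_hits({r: routes[r] for r in consensus_routes})

    res = pd.DataFrame({"log2fc": lfc, "valid": valid})
    for name, hits in routes.items():
        res[name] = [hits.get(fid, "none") for fid in res.index]
    res["consensus"] = [consensus.get(fid, "none") for fid in res.index]
    res.attrs["sigma"] = sigma
    res.attrs["routes"] = routes
    res.attrs["consensus_hits"] = consensus
    return res


# ---------------------------------------------------------------------------
# Sequencing QC arithmetic
# ---------------------------------------------------------------------------

QC_RAW_COLUMNS = ("total_reads", "mapped_reads", "mapped_wo_dup", "properly_paired")


def _load_data_tsv(name: str) -> pd.DataFrame:
    with importlib.resources.files("omicscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_qc_table1() -> pd.DataFrame:
    """Raw per-sample sequencing QC counts (in millions) bundled with the
    package: two HiSeq lanes of 12 libraries each (4 replicates x 3
    conditions per lane)."""
    return _load_data_tsv("qc_table1.tsv")


def load_qc_table1_lane_totals() -> pd.DataFrame:
    """Published per-lane total raw QC counts (in millions).

    The source report's lane totals were summed before its per-sample
    values were rounded for print, so they differ from the sum of the
    rounded per-sample rows by a few hundredths; combined run totals are
    defined as the sum of these lane totals."""
    return _load_data_tsv("qc_table1_lane_totals.tsv")


def qc_summary(
    rows: pd.DataFrame,
    read_length_bp: int = 100,
    transcriptome_size_mb: float = 65.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive QC percentages, sequenced bases and coverage from raw counts.

    ``rows`` must carry ``sample_id`` plus the raw count columns in units of
    10^6 reads (optionally a ``lane`` column).  Derived columns:

    - pct_mapped_wo_dup   = 100 * mapped_wo_dup / total_reads
    - pct_properly_paired = 100 * properly_paired / mapped_wo_dup
    - sequenced_mb        = properly_paired(10^6) * read_length_bp (paired
      reads counted individually at read_length_bp each)
    - coverage_x          = sequenced_mb / transcriptome_size_mb

    Returns (per-sample table, totals table with one row per lane plus a
    combined row; totals are column sums with percentages recomputed).
    """
    df = rows.copy()
    for col in QC_RAW_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing QC column {col!r}")
    hier = (
        (df["properly_paired"] >= 0)
        & (df["properly_paired"] <= df["mapped_wo_dup"])
        & (df["mapped_wo_dup"] <= df["mapped_reads"])
        & (df["mapped_reads"] <= df["total_reads"])
    )
    if not hier.all():
        bad = df.loc[~hier, "sample_id"].iloc[0]
        raise ValueError(f"QC count hierarchy violated for sample {bad!r}")

    def derive(d: pd.DataFrame) -> pd.DataFrame:
        d = d.copy()
        d["pct_mapped_wo_dup"] = 100.0 * d["mapped_wo_dup"] / d["total_reads"]
        d["pct_properly_paired"] = 100.0 * d["properly_paired"] / d["mapped_wo_dup"]
        d["sequenced_mb"] = d["properly_paired"] * read_length_bp
        d["coverage_x"] = d["sequenced_mb"] / transcriptome_size_mb
        return d

    per_sample = derive(df)

    groups: list[pd.DataFrame] = []
    if "lane" in df.columns:
        lane_tot = df.groupby("lane")[list(QC_RAW_COLUMNS)].sum().reset_index()
        lane_tot.insert(0, "sample_id", [f"lane-{l}-total" for l in lane_tot.pop("lane")])
        groups.append(lane_tot)
    combined = df[list(QC_RAW_COLUMNS)].sum().to_frame().T
    combined.insert(0, "sample_id", "combined-total")
    groups.append(combined)
    totals = derive(pd.concat(groups, ignore_index=True))
    return per_sample, totals
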