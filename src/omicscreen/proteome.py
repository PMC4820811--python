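"""Reporter-ion proteome quantification stage.

Works on PSM (peptide-spectrum match) tables in the style of a
Proteome-Discoverer export: one row per spectrum with 8-plex reporter-channel
intensities, an isolation-interference percentage, an identification q-value
and a peptide rank.  The stage is: filter PSMs, aggregate spectra to a
single per-protein value per channel by the median, quantile-normalize
channels, log2-transform, Student's t-test of mutant vs wild-type channels,
and flag differential proteins at a k-sigma cutoff on the log2 fold change
(sigma again the RMS about zero).  Two labelling platforms (e.g., iTRAQ and
TMT) can be reconciled by direction-consistent concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rnaseq import SigmaEstimate, detect_by_sigma, estimate_sigma_zero

PSM_META_COLUMNS = (
    "protein_id",
    "peptide_seq",
    "spectrum_id",
    "rank",
    "q_value",
    "interference_pct",
)


@dataclass
class ChannelMap:
    """Maps intensity column names to (condition, replicate) labels."""

    conditions: dict[str, str]

    @property
    def channels(self) -> list[str]:
        return list(self.conditions)

    def of(self, condition: str) -> list[str]:
        return [c for c, cond in self.conditions.items() if cond == condition]


def default_channel_map() -> ChannelMap:
    """The 8-plex layout used throughout: 3 wild-type, 3 mutant and 2
    non-transfected control channels."""
    layout = {}
    for i in range(1, 4):
        layout[f"wt_{i}"] = "wildtype"
    for i in range(1, 4):
        layout[f"mut_{i}"] = "mutant"
    for i in range(1, 3):
        layout[f"ctl_{i}"] = "control"
    return ChannelMap(layout)


def filter_psms(
    psms: pd.DataFrame,
    max_interference: float = 30.0,
    max_q: float = 0.01,
    top_rank_only: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """PSM-level quality filter.

    Retains rows with isolation interference strictly below
    ``max_interference`` (the conventional "<30%" rule), identification
    q-value <= ``max_q`` (an inclusive 1% FDR cutoff) and, optionally,
    rank-1 peptide assignments only.  Returns the surviving rows and a
    report of input/surviving counts.  An empty survivor set is valid.
    """
    keep = (psms["interference_pct"] < max_interference) & (psms["q_value"] <= max_q)
    if top_rank_only:
        keep &= psms["rank"] == 1
    out = psms.loc[keep].copy()
    report = {
        "n_input": int(len(psms)),
        "n_surviving": int(len(out)),
        "n_removed": int(len(psms) - len(out)),
    }
    return out, report


def aggregate_to_protein(psms: pd.DataFrame, channels: list[str]) -> pd.DataFrame:
    """Collapse spectra to one value per protein per channel by the median.

    An even number of spectra yields the mean of the two central values
    (the standard median).  Also records the number of spectra and distinct
    peptides used per protein.
    """
    grouped = psms.groupby("protein_id")
    med = grouped[channels].median()
    med["n_spectra_used"] = grouped.size()
    med["n_peptides_used"] = grouped["peptide_seq"].nunique()
    return med


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share one empirical distribution.

    Each column's rank r is replaced by the mean of the r-th order statistics
    across columns; ties within a column receive the mean of the reference
    values their ranks span (average-rank convention).  Rows containing
    missing values must be dropped beforehand.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix (drop NaN rows first)")
    if matrix.shape[1] < 2:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = matrix.rank(method="average").to_numpy() - 1.0  # 0-based, may be half-integer
    positions = np.arange(len(reference), dtype=float)
    normalized = np.empty_like(values)
    for j in range(values.shape[1]):
        normalized[:, j] = np.interp(ranks[:, j], positions, reference)
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)


def protein_t_test(
    log2_matrix: pd.DataFrame, mutant_channels: list[str], wildtype_channels: list[str]
) -> pd.DataFrame:
    """Two-sided pooled-variance Student's t-test per protein on log2 values.

    log2fc = mean(mutant) - mean(wildtype).  Degenerate proteins with zero
    variance in both groups get p = 1 when the means are equal and p = 0
    otherwise.  Benjamini-Hochberg q-values are appended.
    """
    if len(mutant_channels) < 2 or len(wildtype_channels) < 2:
        raise ValueError("need >=2 channels per group for a t-test")
    mut = log2_matrix[mutant_channels].to_numpy(dtype=float)
    wt = log2_matrix[wildtype_channels].to_numpy(dtype=float)
    lfc = mut.mean(axis=1) - wt.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(mut, wt, axis=1)
    degenerate = np.isnan(p)
    p = np.where(degenerate, np.where(np.isclose(lfc, 0.0), 1.0, 0.0), p)
    res = pd.DataFrame({"log2fc": lfc, "p": p}, index=log2_matrix.index)
    res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


def detect_proteins_by_sigma(
    log2fc: pd.Series, k: int = 3
) -> tuple[dict[str, str], SigmaEstimate]:
    """k-sigma differential-protein flags on the log2FC vector.

    Sigma is the RMS of the vector about zero, identical in contract to the
    transcriptome thresholding rule.
    """
    sigma = estimate_sigma_zero(log2fc)
    return detect_by_sigma(log2fc, sigma, k=k), sigma


def cross_platform_concordance(
    hits_a: dict[str, str], hits_b: dict[str, str], shared_universe: set[str] | None = None
) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
    """Reconcile two labelling platforms.

    Concordant proteins are hit on both platforms with the same direction;
    proteins hit on both with opposite directions are reported as discordant
    (direction pair per platform).  If ``shared_universe`` is given, hits
    outside it are ignored.
    """
    keys = set(hits_a) & set(hits_b)
    if shared_universe is not None:
        keys &= set(shared_universe)
    concordant: dict[str, str] = {}
    discordant: dict[str, tuple[str, str]] = {}
    for pid in keys:
        if hits_a[pid] == hits_b[pid]:
            concordant[pid] = hits_a[pid]
        else:
            discordant[pid] = (hits_a[pid], hits_b[pid])
    return concordant, discordant


def run_proteome_pipeline(
    psms: pd.DataFrame,
    channel_map: ChannelMap | None = None,
    max_interference: float = 30.0,
    max_q: float = 0.01,
    k: int = 3,
    median_center: bool = False,
) -> dict:
    """Full single-platform pipeline: filter -> median aggregate -> quantile
    normalize -> log2 -> t-test -> k-sigma flags.

    Control channels ride through normalization but are excluded from the
    mutant-vs-wild-type test.  Proteins with a missing channel after
    aggregation are dropped rather than imputed.  ``median_center``
    optionally median-centers each channel after quantile normalization
    (off by default).
    """
    cmap = channel_map or default_channel_map()
    channels = cmap.channels
    filtered, report = filter_psms(
        psms, max_interference=max_interference, max_q=max_q, top_rank_only=True
    )
    if filtered.empty:
        return {"filter_report": report, "hits": {}, "matrix": pd.DataFrame(), "tests": pd.DataFrame()}
    protein = aggregate_to_protein(filtered, channels)
    complete = protein[channels].notna().all(axis=1) & (protein[channels] > 0).all(axis=1)
    mat = quantile_normalize(protein.loc[complete, channels])
    log_mat = np.log2(mat)
    if median_center:
        log_mat = log_mat - log_mat.median(axis=0)
    tests = protein_t_test(log_mat, cmap.of("mutant"), cmap.of("wildtype"))
    hits, sigma = detect_proteins_by_sigma(tests["log2fc"], k=k)
    tests["sigma_hit"] = [hits.get(pid, "none") for pid in tests.index]
    return {
        "filter_report": report,
        "protein_matrix": protein,
        "normalized_log2": log_mat,
        "tests": tests,
        "sigma": sigma,
        "hits": hits,
    }


def psm_table_to_tsv(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def psm_table_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PSM_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    return df
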