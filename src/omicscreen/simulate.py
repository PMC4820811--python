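"""Synthetic-data generators with planted truth for every pipeline stage.

Each generator emulates the statistical structure of the real study design
so that downstream operations are testable without any external download:

- RNA-seq: 3 conditions (non-transfected control, wild-type, mutant) x 8
  biological replicates of negative-binomial gene counts.  Every gene's
  mean splits into a background component, shared by all conditions and
  alone constituting the control mean, plus a transfection signal; planted
  mutant-vs-wild-type effects scale the signal component so that the
  background-subtraction step recovers them.
- Reporter-ion proteomics: 8-plex PSM tables (3 wild-type + 3 mutant + 2
  control channels) with several spectra per peptide and peptides per
  protein, log-normal spectrum-level noise, and configurable fractions of
  rows failing the interference / FDR / rank filters.  Planted protein
  effects multiply the mutant channels so that median aggregation is the
  correct de-noiser.
- Pedigrees: gene-drop simulation of a diallelic disease locus linked to a
  codominant marker at recombination fraction theta, with affection status
  drawn from the penetrance vector (deterministic under 0/1 penetrances).
- qPCR Ct tables: Gaussian noise on the Ct scale around group means that
  encode known fold changes.

Random streams are seeded independently per generator (a fixed stream
offset is mixed into the seed) so, e.g., enlarging the gene panel does not
perturb a pedigree simulated from the same master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .linkage import AFFECTED, Individual, Pedigree, UNAFFECTED
from .rnaseq import CountMatrix

TIER_NULL = "null"
TIER_TRANSCRIPT = "transcript_only"
TIER_PROTEIN = "protein_only"
TIER_BOTH = "both"

_STREAMS = {"rnaseq": 11, "psm": 23, "pedigree": 37, "ct": 53}


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Shared configuration for the omics generators.

    Parameters
    ----------
    n_genes
        Number of features to simulate.
    n_replicates
        Biological replicates per condition (>= 2; the study design used 8).
    baseline_mean_log
        Natural-log mean of the log-normal distribution of per-gene baseline
        expression.
    baseline_sd_log
        Natural-log s.d. of that distribution.
    dispersion
        Negative-binomial dispersion d, with var = mu + d * mu^2.
    background_fraction
        For a transfection-responsive gene, the share of its mean present
        identically in all conditions; the control mean carries only this
        background component.
    responsive_fraction
        Fraction of genes that respond to transfection at all.  The rest
        are pure background: expressed identically in control, wild-type
        and mutant, the way most of a real transcriptome behaves.  Planted
        effect features are always responsive.
    effect_table
        Sequence of (feature_id, log2_effect) planted for mutant vs
        wild-type on the signal component.
    gene_length_range
        Inclusive bp interval for simulated transcript lengths.
    size_factor_sd
        Log-normal s.d. of per-sample library-size jitter (0 = equal
        depths).
    seed
        Master seed; each generator derives an independent stream from it.
    """

    n_genes: int = 2000
    n_replicates: int = 8
    baseline_mean_log: float = 6.0
    baseline_sd_log: float = 1.0
    dispersion: float = 0.05
    background_fraction: float = 0.25
    responsive_fraction: float = 0.3
    effect_table: Sequence[tuple[str, float]] = field(default_factory=tuple)
    gene_length_range: tuple[int, int] = (200, 10_000)
    size_factor_sd: float = 0.1
    seed: int = 0

    def validate(self, feature_ids: Sequence[str] | None = None) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be a positive integer")
        if self.n_replicates < 2:
            raise SimConfigError("n_replicates must be >= 2 (t-tests need 2 per group)")
        if self.dispersion <= 0:
            raise SimConfigError("dispersion must be > 0")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise SimConfigError("background_fraction must lie in [0, 1]")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise SimConfigError("responsive_fraction must lie in [0, 1]")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise SimConfigError("gene_length_range must be a positive interval")
        if self.size_factor_sd < 0:
            raise SimConfigError("size_factor_sd must be >= 0")
        ids = self.feature_ids() if feature_ids is None else list(feature_ids)
        unknown = {fid for fid, _ in self.effect_table} - set(ids)
        if unknown:
            raise SimConfigError(
                f"effect_table features not in generated panel: {sorted(unknown)[:5]}"
            )

    def feature_ids(self) -> list[str]:
        return [f"gene_{i:05d}" for i in range(self.n_genes)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


def _truth_table(cfg: SimConfig, tier: str) -> pd.DataFrame:
    effects = dict(cfg.effect_table)
    ids = cfg.feature_ids()
    return pd.DataFrame(
        {
            "feature_id": ids,
            "true_log2fc": [effects.get(f, 0.0) for f in ids],
            "tier": [tier if f in effects and effects[f] != 0 else TIER_NULL for f in ids],
        }
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = mu + d mu^2)."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def simulate_rnaseq_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the 3 x n_replicates count matrix plus its truth table.

    A ``responsive_fraction`` share of genes responds to transfection: for
    those, with baseline mean m and background fraction f, the means are
    control = f*m, wild-type = m, mutant = f*m + (1-f)*m * 2**effect.  The
    remaining genes are pure background, expressed at m in every condition,
    so depth normalization stays anchored and background subtraction
    cancels them rather than the responsive signal.  Planted effect
    features are always responsive.
    """
    cfg.validate()
    rng = cfg.rng("rnaseq")
    ids = cfg.feature_ids()
    m = rng.lognormal(cfg.baseline_mean_log, cfg.baseline_sd_log, size=cfg.n_genes)
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, cfg.n_genes)
    effects = dict(cfg.effect_table)
    e = np.array([effects.get(f, 0.0) for f in ids])
    responsive = rng.random(cfg.n_genes) < cfg.responsive_fraction
    responsive |= e != 0.0
    background = np.where(responsive, cfg.background_fraction * m, m)
    signal = np.where(responsive, (1.0 - cfg.background_fraction) * m, 0.0)
    cond_mean = {
        "control": background,
        "wildtype": background + signal,
        "mutant": background + signal * 2.0**e,
    }
    cols, data, meta = [], [], []
    for cond in ("control", "wildtype", "mutant"):
        for r in range(1, cfg.n_replicates + 1):
            sf = rng.lognormal(0.0, cfg.size_factor_sd) if cfg.size_factor_sd > 0 else 1.0
            counts = _nb_draw(rng, cond_mean[cond] * sf, cfg.dispersion)
            name = f"{cond}_{r}"
            cols.append(name)
            data.append(counts)
            meta.append({"sample_id": name, "condition": cond, "replicate": r})
    counts_df = pd.DataFrame(np.column_stack(data), index=pd.Index(ids, name="feature_id"), columns=cols)
    samples = pd.DataFrame(meta).set_index("sample_id")
    cm = CountMatrix(counts=counts_df, lengths=pd.Series(lengths, index=counts_df.index), samples=samples)
    return cm, _truth_table(cfg, TIER_TRANSCRIPT)


def simulate_psm_table(
    cfg: SimConfig,
    platform_label: str = "itraq",
    n_proteins: int = 500,
    interference_exceed_fraction: float = 0.1,
    q_exceed_fraction: float = 0.05,
    low_rank_fraction: float = 0.05,
    spectrum_noise_sd_log2: float = 0.25,
    max_peptides: int = 10,
    max_spectra: int = 5,
    abundances: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an 8-plex PSM table with planted protein effects.

    Per protein: 1-10 peptides with 1-5 spectra each.  Channel layout is 3
    wild-type + 3 mutant + 2 control.  Spectrum intensities are the channel
    mean times a per-spectrum ionization factor times log-normal noise;
    planted effects multiply the mutant channels; control channels carry
    only the background fraction.  Configurable fractions of rows exceed
    the interference, q-value and rank filters.

    ``abundances`` optionally fixes the per-protein base abundances (one
    per protein).  Two platform runs given the same array emulate two
    labelling chemistries measuring the same lysates: shared protein
    amounts, independent measurement noise.
    """
    ids = [f"prot_{i:05d}" for i in range(n_proteins)]
    cfg.validate(feature_ids=ids)
    for name, frac in (
        ("interference_exceed_fraction", interference_exceed_fraction),
        ("q_exceed_fraction", q_exceed_fraction),
        ("low_rank_fraction", low_rank_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise SimConfigError(f"{name} must lie in [0, 1]")
    # fold the platform label into the stream so iTRAQ and TMT runs differ
    label_offset = sum(ord(c) for c in platform_label) % 1000
    rng = np.random.default_rng([_STREAMS["psm"], label_offset, cfg.seed])
    effects = dict(cfg.effect_table)
    if abundances is not None:
        abundance = np.asarray(abundances, dtype=float)
        if abundance.shape != (n_proteins,):
            raise SimConfigError("abundances must have one entry per protein")
    else:
        abundance = rng.lognormal(cfg.baseline_mean_log, cfg.baseline_sd_log, size=n_proteins)
    channels = [f"wt_{i}" for i in (1, 2, 3)] + [f"mut_{i}" for i in (1, 2, 3)] + [
        f"ctl_{i}" for i in (1, 2)
    ]
    rows = []
    spec_counter = 0
    for pid, ab in zip(ids, abundance):
        e = effects.get(pid, 0.0)
        ch_mean = np.array(
            [ab] * 3 + [ab * 2.0**e] * 3 + [ab * cfg.background_fraction] * 2
        )
        n_pep = int(rng.integers(1, max_peptides + 1))
        for pep in range(n_pep):
            pep_seq = f"{pid}_pep{pep}"
            pep_factor = rng.lognormal(0.0, 0.5)
            n_spec = int(rng.integers(1, max_spectra + 1))
            for _ in range(n_spec):
                spec_counter += 1
                noise = 2.0 ** rng.normal(0.0, spectrum_noise_sd_log2, size=8)
                intensities = ch_mean * pep_factor * noise
                fail_int = rng.random() < interference_exceed_fraction
                interference = (
                    rng.uniform(30.0, 100.0) if fail_int else rng.uniform(0.0, 30.0)
                )
                fail_q = rng.random() < q_exceed_fraction
                q = rng.uniform(0.011, 0.2) if fail_q else rng.uniform(0.0, 0.01)
                rank = 2 if rng.random() < low_rank_fraction else 1
                rows.append(
                    {
                        "protein_id": pid,
                        "peptide_seq": pep_seq,
                        "spectrum_id": f"{platform_label}_spec{spec_counter:06d}",
                        "rank": rank,
                        "q_value": q,
                        "interference_pct": interference,
                        **{c: v for c, v in zip(channels, intensities)},
                    }
                )
    psms = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "true_log2fc": [effects.get(f, 0.0) for f in ids],
            "tier": [
                TIER_PROTEIN if effects.get(f, 0.0) != 0 else TIER_NULL for f in ids
            ],
        }
    )
    return psms, truth


def simulate_pedigree(
    structure: Sequence[tuple[str, str | None, str | None, str]],
    theta: float,
    marker_allele_freqs,
    disease_allele_freq: float = 0.001,
    seed: int = 0,
    penetrances: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> Pedigree:
    """Gene-drop simulation over a pedigree structure.

    ``structure`` lists (id, father, mother, sex) with None parents marking
    founders (parents must precede children).  Founder haplotypes are drawn
    from population frequencies assuming linkage equilibrium; transmissions
    recombine with probability ``theta``.  Affection is drawn from the
    penetrance vector, hence deterministic under full penetrance.  All
    individuals are marker-genotyped.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    freqs = np.asarray(marker_allele_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("marker allele frequencies must sum to 1")
    rng = np.random.default_rng([_STREAMS["pedigree"], seed])
    ped = Pedigree()
    # haplotype = (disease allele: 0=D 1=d, marker allele 0-based)
    haplos: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}

    def draw_founder_hap() -> tuple[int, int]:
        d = 0 if rng.random() < disease_allele_freq else 1
        m = int(rng.choice(len(freqs), p=freqs))
        return d, m

    def transmit(parent: str) -> tuple[int, int]:
        hp, hm = haplos[parent]
        first = hp if rng.random() < 0.5 else hm
        other = hm if first is hp else hp
        if rng.random() < theta:  # recombinant: marker allele from the other strand
            return (first[0], other[1])
        return first

    for iid, fa, mo, sex in structure:
        if (fa is None) != (mo is None):
            raise ValueError(f"individual {iid!r} has exactly one parent")
        if fa is None:
            h = (draw_founder_hap(), draw_founder_hap())
        else:
            if fa not in haplos or mo not in haplos:
                raise ValueError(f"parents of {iid!r} must be listed first")
            h = (transmit(fa), transmit(mo))
        haplos[iid] = h
        n_d = (h[0][0] == 0) + (h[1][0] == 0)  # copies of the disease allele
        pen = penetrances[n_d]  # penetrances indexed by disease-allele count
        affected = rng.random() < pen if 0.0 < pen < 1.0 else pen == 1.0
        ped.add(
            Individual(
                id=iid,
                father=fa,
                mother=mo,
                sex=sex,
                affection=AFFECTED if affected else UNAFFECTED,
                genotype=(h[0][1] + 1, h[1][1] + 1),
            )
        )
    ped.validate()
    ped.meioses = haplos  # type: ignore[attr-defined]  # exposed for tests
    return ped


def random_pedigree_structure(
    n_members: int, rng: np.random.Generator
) -> list[tuple[str, str | None, str | None, str]]:
    """Random loopless pedigree structure with ``n_members`` individuals.

    Draws among nuclear families of varying sibship size and, for six or
    more members, three-generation structures.  Parents precede children,
    as :func:`simulate_pedigree` requires.
    """
    if n_members < 3:
        raise ValueError("a pedigree needs at least 3 members")
    struct: list[tuple[str, str | None, str | None, str]] = [
        ("f", None, None, "male"),
        ("m", None, None, "female"),
    ]
    if n_members >= 6 and rng.random() < 0.5:
        # three generations: founder couple, their child marries in, grandkids
        struct += [
            ("c1", "f", "m", "male"),
            ("spouse", None, None, "female"),
        ]
        for i in range(n_members - 4):
            struct.append((f"g{i}", "c1", "spouse", "male" if i % 2 else "female"))
    else:
        for i in range(n_members - 2):
            struct.append((f"c{i}", "f", "m", "male" if i % 2 else "female"))
    return struct


def simulate_ct_table(
    groups: Sequence[tuple[str, float, int]],
    ct_ref_mean: float = 20.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    ct_target_calibrator: float = 25.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table; the first group is the calibrator.

    ``groups`` lists (label, true_fold, n_replicates).  The target-gene Ct
    of a group with fold F is the calibrator target Ct minus log2(F) plus
    Gaussian noise; reference-gene Cts scatter around ``ct_ref_mean``.
    """
    rng = np.random.default_rng([_STREAMS["ct"], seed])
    rows = []
    for label, fold, n in groups:
        if fold <= 0:
            raise ValueError(f"true_fold must be > 0 (group {label!r})")
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample": f"{label}_{r}",
                    "group": label,
                    "ct_target": ct_target_calibrator
                    - np.log2(fold)
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                    "ct_reference": ct_ref_mean
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                }
            )
    return pd.DataFrame(rows)


def simulate_joint_omics(
    cfg: SimConfig,
    tier_counts: dict[str, int] | None = None,
    effect_log2: float = 2.5,
    n_proteins: int = 400,
    **psm_kwargs,
) -> dict:
    """Joint transcript + two-platform protein fixture with tiered truth.

    Features are assigned tiers (``both``, ``transcript_only``,
    ``protein_only``, rest ``null``); tier=both features carry the same
    signed effect in both omics layers.  Feature ids are shared across
    layers (identity mapping), and so are protein base abundances: both
    platform runs measure the same simulated lysates.  Effects are planted
    on mid-abundance (10th-90th percentile) proteins, since isobaric
    quantification compresses ratios at the detection floor (rank-based
    normalization cannot represent values below the shared reference), so
    planted truth at the extremes would be unrecoverable by any analysis
    of such data.  Returns a dict with the count matrix, two PSM tables
    (platform labels ``itraq``/``tmt``) and the combined truth table.
    """
    tier_counts = tier_counts or {TIER_BOTH: 6, TIER_TRANSCRIPT: 6, TIER_PROTEIN: 6}
    n_feat = min(cfg.n_genes, n_proteins)
    ids = [f"gene_{i:05d}" for i in range(n_feat)]
    rng = np.random.default_rng([97, cfg.seed])
    abundances = rng.lognormal(cfg.baseline_mean_log, cfg.baseline_sd_log, size=n_feat)
    lo, hi = np.quantile(abundances, [0.1, 0.9])
    eligible = np.flatnonzero((abundances >= lo) & (abundances <= hi))
    n_needed = sum(tier_counts.values())
    chosen = list(rng.choice(eligible, size=n_needed, replace=False))
    tiers: dict[str, str] = {}
    signs: dict[str, float] = {}
    pos = 0
    for tier, cnt in tier_counts.items():
        for _ in range(cnt):
            fid = ids[chosen[pos]]
            tiers[fid] = tier
            signs[fid] = effect_log2 * (1.0 if rng.random() < 0.5 else -1.0)
            pos += 1
    t_effects = [
        (fid, signs[fid]) for fid, t in tiers.items() if t in (TIER_BOTH, TIER_TRANSCRIPT)
    ]
    p_effects = [
        (fid, signs[fid]) for fid, t in tiers.items() if t in (TIER_BOTH, TIER_PROTEIN)
    ]

    from dataclasses import replace

    cm, _ = simulate_rnaseq_counts(replace(cfg, effect_table=tuple(t_effects)))
    pcfg = replace(cfg, effect_table=tuple(p_effects))
    # protein panel must share the feature-id namespace and lysate amounts
    psm_a, _ = _simulate_psm_named(pcfg, "itraq", ids, abundances=abundances, **psm_kwargs)
    psm_b, _ = _simulate_psm_named(pcfg, "tmt", ids, abundances=abundances, **psm_kwargs)
    truth = pd.DataFrame(
        {
            "feature_id": cfg.feature_ids(),
            "true_log2fc": [signs.get(f, 0.0) for f in cfg.feature_ids()],
            "tier": [tiers.get(f, TIER_NULL) for f in cfg.feature_ids()],
        }
    )
    return {"counts": cm, "psm_itraq": psm_a, "psm_tmt": psm_b, "truth": truth}


def _simulate_psm_named(cfg: SimConfig, platform_label: str, ids: list[str], **kwargs):
    """simulate_psm_table with an externally supplied protein-id panel."""
    from dataclasses import replace

    to_prot = {fid: f"prot_{i:05d}" for i, fid in enumerate(ids)}
    cfg2 = replace(
        cfg,
        effect_table=tuple((to_prot[f], e) for f, e in cfg.effect_table if f in to_prot),
    )
    psms, truth = simulate_psm_table(cfg2, platform_label, n_proteins=len(ids), **kwargs)
    rename = {v: k for k, v in to_prot.items()}
    psms = psms.assign(protein_id=psms["protein_id"].map(rename))
    truth = truth.assign(feature_id=truth["feature_id"].map(rename))
    return psms, truth
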