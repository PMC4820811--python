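"""Parametric two-point linkage analysis.

Computes the likelihood of a pedigree's affection statuses and marker
genotypes under a two-locus model: a diallelic disease locus with a
penetrance vector (f_DD, f_Dd, f_dd) and a codominant marker with supplied
allele frequencies, joined by a sex-averaged recombination fraction theta.
Founder genotypes follow Hardy-Weinberg proportions with linkage
equilibrium between the loci.  The LOD score is

    Z(theta) = log10 L(theta) - log10 L(0.5),

with Z(0.5) = 0 by construction and Z(0) = -inf in the presence of an
obligate recombinant.

The likelihood engine is generalized Elston-Stewart peeling implemented as
variable elimination on the pedigree's factor graph (founder priors,
transmission factors, penetrance/marker observation factors) with a greedy
minimum-degree elimination order.  Because variable elimination is exact on
arbitrary factor graphs, consanguineous (looped) pedigrees are handled by
the same engine without loop breaking.  A brute-force enumeration over the
full joint ordered-genotype space is provided for small pedigrees as an
independent reference.

Individual state space: ordered two-locus genotypes.  A haplotype is a
(disease allele, marker allele) pair; an ordered genotype is a (paternal
haplotype, maternal haplotype) pair, giving (2*m)**2 states for an
m-allele marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

# LINKAGE-format affection codes (pre-makeped dialect)
_AFFECTION_CODES = {"0": UNKNOWN, "1": UNAFFECTED, "2": AFFECTED}


class PedigreeError(ValueError):
    """Raised for malformed pedigrees or .ped files."""


@dataclass
class Individual:
    id: str
    father: str | None
    mother: str | None
    sex: str
    affection: str = UNKNOWN
    genotype: tuple[int, int] | None = None  # unordered marker allele pair, 1-based

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class DiseaseModel:
    """Disease-locus model: allele frequency plus a penetrance vector.

    ``penetrances[k]`` is the probability of affection given ``k`` copies of
    the disease allele (the triple f_DD, f_Dd, f_dd with D the wild-type
    allele).  The default (0, 0, 1) with a disease allele frequency of
    0.001 is the fully penetrant autosomal recessive model; (0, 1, 1) is
    fully penetrant dominance.
    """

    disease_allele_freq: float = 0.001
    penetrances: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease allele frequency must be in (0, 1)")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")


@dataclass
class Pedigree:
    members: dict[str, Individual] = field(default_factory=dict)
    family_id: str = "1"

    def add(self, ind: Individual) -> None:
        if ind.id in self.members:
            raise PedigreeError(f"duplicate individual id {ind.id!r}")
        self.members[ind.id] = ind

    def validate(self) -> None:
        for ind in self.members.values():
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(f"individual {ind.id!r} has exactly one parent")
            for pid in (ind.father, ind.mother):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        # acyclicity via DFS over parent links
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise PedigreeError(f"individual {iid!r} is its own ancestor")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self.members[iid]
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    visit(pid)
            state[iid] = 2

        for iid in self.members:
            visit(iid)

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.is_founder]

    def has_loops(self) -> bool:
        """True iff the marriage graph contains a cycle (consanguinity or
        marriage loops).  Nodes: individuals plus matings; edges: mate-mating
        and mating-child.  A loopless pedigree yields a forest."""
        nodes: set[str] = set(self.members)
        edges: set[tuple[str, str]] = set()
        for ind in self.members.values():
            if ind.is_founder:
                continue
            mating = f"mating:{ind.father}+{ind.mother}"
            nodes.add(mating)
            edges.add((ind.father, mating))
            edges.add((ind.mother, mating))
            edges.add((mating, ind.id))
        # count connected components with union-find
        parent = {n: n for n in nodes}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        n_components = len({find(n) for n in nodes})
        return len(edges) > len(nodes) - n_components


def parse_linkage_ped(source) -> list[Pedigree]:
    """Parse a pre-makeped LINKAGE .ped file.

    Whitespace-delimited columns: famid, id, father, mother, sex, affection,
    allele1, allele2 with 0 denoting a missing parent/genotype and affection
    coded 0=unknown, 1=unaffected, 2=affected.  Returns one Pedigree per
    family id, in order of first appearance.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    peds: dict[str, Pedigree] = {}
    for lineno, line in enumerate(lines, start=1):
        fieldsv = line.split()
        if not fieldsv or line.lstrip().startswith("#"):
            continue
        if len(fieldsv) < 8:
            raise PedigreeError(f"line {lineno}: expected 8 columns, got {len(fieldsv)}")
        fam, iid, fa, mo, sex, aff, a1, a2 = fieldsv[:8]
        if aff not in _AFFECTION_CODES:
            raise PedigreeError(f"line {lineno}: bad affection code {aff!r}")
        try:
            a1i, a2i = int(a1), int(a2)
        except ValueError as exc:
            raise PedigreeError(f"line {lineno}: bad allele columns") from exc
        if (a1i == 0) != (a2i == 0):
            raise PedigreeError(f"line {lineno}: half-missing genotype for {iid!r}")
        ped = peds.setdefault(fam, Pedigree(family_id=fam))
        ped.add(
            Individual(
                id=iid,
                father=None if fa == "0" else fa,
                mother=None if mo == "0" else mo,
                sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                affection=_AFFECTION_CODES[aff],
                genotype=None if a1i == 0 else (a1i, a2i),
            )
        )
    for ped in peds.values():
        ped.validate()
    return list(peds.values())


def write_linkage_ped(ped: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {UNKNOWN: "0", UNAFFECTED: "1", AFFECTED: "2"}
    with open(path, "w") as fh:
        for ind in ped.members.values():
            g = ind.genotype or (0, 0)
            fh.write(
                f"{ped.family_id} {ind.id} {ind.father or 0} {ind.mother or 0} "
                f"{sex_code[ind.sex]} {aff_code[ind.affection]} {g[0]} {g[1]}\n"
            )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


class _StateSpace:
    """Indexing helpers over ordered two-locus genotypes."""

    def __init__(self, n_marker_alleles: int):
        self.m = n_marker_alleles
        self.n_hap = 2 * n_marker_alleles
        self.n_geno = self.n_hap**2
        # haplotype h -> (disease allele in {0:D, 1:d}, marker allele 0-based)
        self.hap_d = np.repeat(np.arange(2), n_marker_alleles)
        self.hap_m = np.tile(np.arange(n_marker_alleles), 2)
        self.g_pat, self.g_mat = np.divmod(np.arange(self.n_geno), self.n_hap)

    def disease_genotype(self) -> np.ndarray:
        """Number of disease (D) alleles per ordered genotype: 0, 1 or 2."""
        return (self.hap_d[self.g_pat] == 0).astype(int) + (self.hap_d[self.g_mat] == 0).astype(int)

    def marker_pair(self) -> tuple[np.ndarray, np.ndarray]:
        return self.hap_m[self.g_pat], self.hap_m[self.g_mat]


def _founder_prior(ss: _StateSpace, model: DiseaseModel, marker_freqs: np.ndarray) -> np.ndarray:
    p_d = np.array([model.disease_allele_freq, 1.0 - model.disease_allele_freq])
    hap_p = p_d[ss.hap_d] * marker_freqs[ss.hap_m]
    return hap_p[ss.g_pat] * hap_p[ss.g_mat]


def _transmission(ss: _StateSpace, theta: float) -> np.ndarray:
    """T[g, h] = P(parent with ordered genotype g transmits haplotype h)."""
    T = np.zeros((ss.n_geno, ss.n_hap))
    for g in range(ss.n_geno):
        hp, hm = ss.g_pat[g], ss.g_mat[g]
        # parental haplotypes pass intact with probability (1-theta)/2 each
        T[g, hp] += (1.0 - theta) / 2.0
        T[g, hm] += (1.0 - theta) / 2.0
        # recombinants swap the marker allele between the two haplotypes
        r1 = ss.hap_d[hp] * ss.m + ss.hap_m[hm]
        r2 = ss.hap_d[hm] * ss.m + ss.hap_m[hp]
        T[g, r1] += theta / 2.0
        T[g, r2] += theta / 2.0
    return T


def _observation(ss: _StateSpace, ind: Individual, model: DiseaseModel) -> np.ndarray:
    """Penetrance x marker-compatibility factor for one individual."""
    n_d = ss.disease_genotype()  # copies of the disease allele
    pen_by_nd = np.asarray(model.penetrances, dtype=float)
    if ind.affection == AFFECTED:
        obs = pen_by_nd[n_d]
    elif ind.affection == UNAFFECTED:
        obs = 1.0 - pen_by_nd[n_d]
    else:
        obs = np.ones(ss.n_geno)
    if ind.genotype is not None:
        mp, mm = ss.marker_pair()
        a, b = ind.genotype[0] - 1, ind.genotype[1] - 1
        match = ((mp == a) & (mm == b)) | ((mp == b) & (mm == a))
        obs = obs * match
    return np.asarray(obs, dtype=float)


def _build_factors(
    ped: Pedigree, model: DiseaseModel, marker_freqs: np.ndarray, theta: float
) -> tuple[list[tuple[tuple[str, ...], np.ndarray]], _StateSpace]:
    ss = _StateSpace(len(marker_freqs))
    T = _transmission(ss, theta)
    prior = _founder_prior(ss, model, marker_freqs)
    # child ordered genotype c = paternal hap * n_hap + maternal hap
    trans = np.zeros((ss.n_geno, ss.n_geno, ss.n_geno))  # [c, f, m]
    Tf = T[:, ss.g_pat]  # [f, c] prob father transmits child's paternal hap
    Tm = T[:, ss.g_mat]  # [m, c]
    trans = Tf.T[:, :, None] * Tm.T[:, None, :]  # [c, f, m]
    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for ind in ped.members.values():
        if ind.is_founder:
            factors.append(((ind.id,), prior.copy()))
        else:
            factors.append(((ind.id, ind.father, ind.mother), trans))
        factors.append(((ind.id,), _observation(ss, ind, model)))
    return factors, ss


def _eliminate(
    factors: list[tuple[tuple[str, ...], np.ndarray]], variables: list[str]
) -> float:
    """Sum-product variable elimination; returns log-likelihood.

    Uses a greedy minimum-degree order on the factor interaction graph and
    rescales intermediate factors to keep arithmetic in a safe range,
    accumulating the log of the normalizers (log-domain overall).
    """
    neighbors: dict[str, set[str]] = {v: set() for v in variables}
    for vars_, _ in factors:
        for a in vars_:
            neighbors[a].update(set(vars_) - {a})
    remaining = set(variables)
    work = list(factors)
    log_scale = 0.0

    while remaining:
        v = min(remaining, key=lambda x: (len(neighbors[x] & remaining), x))
        involved = [f for f in work if v in f[0]]
        work = [f for f in work if v not in f[0]]
        all_vars: list[str] = []
        for vars_, _ in involved:
            for a in vars_:
                if a not in all_vars:
                    all_vars.append(a)
        # align each factor to all_vars order, then broadcast-multiply
        prod = None
        for vars_, arr in involved:
            view_shape = [1] * len(all_vars)
            for pos, a in enumerate(all_vars):
                if a in vars_:
                    view_shape[pos] = arr.shape[vars_.index(a)]
            perm = sorted(range(len(vars_)), key=lambda i: all_vars.index(vars_[i]))
            arr_t = np.transpose(arr, perm)
            arr_b = arr_t.reshape(view_shape)
            prod = arr_b if prod is None else prod * arr_b
        axis = all_vars.index(v)
        summed = prod.sum(axis=axis)
        new_vars = tuple(a for a in all_vars if a != v)
        mx = summed.max()
        if mx == 0.0:
            return -math.inf
        summed = summed / mx
        log_scale += math.log(mx)
        for a in new_vars:
            neighbors[a].update(set(new_vars) - {a})
        if new_vars:
            work.append((new_vars, summed))
        else:
            log_scale += math.log(float(summed))
        remaining.discard(v)

    for vars_, arr in work:  # fully-constant leftovers
        log_scale += math.log(float(arr))
    return log_scale


def pedigree_likelihood(
    ped: Pedigree,
    model: DiseaseModel,
    marker_freqs,
    theta: float,
) -> float:
    """Natural-log likelihood of the pedigree data at recombination
    fraction ``theta``.

    Sums over unobserved two-locus ordered genotypes with Hardy-Weinberg,
    linkage-equilibrium founder priors.  Returns ``-inf`` for data that are
    impossible at this theta (e.g., an obligate recombinant at theta = 0).
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    marker_freqs = np.asarray(marker_freqs, dtype=float)
    if abs(marker_freqs.sum() - 1.0) > 1e-9:
        raise ValueError("marker allele frequencies must sum to 1")
    ped.validate()
    factors, _ = _build_factors(ped, model, marker_freqs, theta)
    return _eliminate(factors, list(ped.members))


def enumerate_likelihood(
    ped: Pedigree,
    model: DiseaseModel,
    marker_freqs,
    theta: float,
    max_members: int = 6,
) -> float:
    """Brute-force reference likelihood over the full joint genotype space.

    Builds the complete (n_geno ** n_members) joint array and sums it, so it
    is only feasible for small pedigrees (state space 16 per individual for
    a 2-allele marker); ``max_members`` guards against runaway memory.
    """
    marker_freqs = np.asarray(marker_freqs, dtype=float)
    if abs(marker_freqs.sum() - 1.0) > 1e-9:
        raise ValueError("marker allele frequencies must sum to 1")
    ids = list(ped.members)
    if len(ids) > max_members:
        raise ValueError(f"enumeration limited to {max_members} members")
    factors, ss = _build_factors(ped, model, marker_freqs, theta)
    n = len(ids)
    joint = np.ones((ss.n_geno,) * n)
    for vars_, arr in factors:
        shape = [1] * n
        perm = sorted(range(len(vars_)), key=lambda i: ids.index(vars_[i]))
        arr_t = np.transpose(arr, perm) if arr.ndim > 1 else arr
        for a in vars_:
            shape[ids.index(a)] = ss.n_geno
        joint = joint * arr_t.reshape(shape)
    total = float(joint.sum())
    return math.log(total) if total > 0.0 else -math.inf


DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def lod_score(ped: Pedigree, model: DiseaseModel, marker_freqs, theta: float) -> float:
    """Two-point LOD: Z(theta) = log10 L(theta) - log10 L(0.5)."""
    if theta == 0.5:
        return 0.0
    ll = pedigree_likelihood(ped, model, marker_freqs, theta)
    ll_half = pedigree_likelihood(ped, model, marker_freqs, 0.5)
    if ll == -math.inf:
        return -math.inf
    return (ll - ll_half) / math.log(10.0)


@dataclass
class LodProfile:
    thetas: tuple[float, ...]
    lods: tuple[float, ...]

    @property
    def max_lod(self) -> float:
        return max(self.lods)

    @property
    def argmax_theta(self) -> float:
        return self.thetas[int(np.argmax(self.lods))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"theta": self.thetas, "lod": self.lods})


def lod_profile(
    ped: Pedigree,
    model: DiseaseModel,
    marker_freqs,
    theta_grid=DEFAULT_THETA_GRID,
) -> LodProfile:
    """LOD scores over a theta grid with the maximizer reported."""
    ll_half = pedigree_likelihood(ped, model, marker_freqs, 0.5)
    lods = []
    for th in theta_grid:
        if th == 0.5:
            lods.append(0.0)
            continue
        ll = pedigree_likelihood(ped, model, marker_freqs, th)
        lods.append(-math.inf if ll == -math.inf else (ll - ll_half) / math.log(10.0))
    return LodProfile(thetas=tuple(theta_grid), lods=tuple(lods))
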