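"""Clonal discrimination and population-genetic statistics for
codominant multilocus (microsatellite) genotypes.

The workflow mirrors standard practice for clonal plants: ramets
(sampled shoots) are grouped into multilocus genotypes (MLGs); repeated
MLGs are tested with Psex — the probability that identical genotypes
arise from distinct sexual events — and merged into genets when
Psex < 0.01; diversity statistics are then computed on the genet-level
dataset: clonal richness R = (G-1)/(N-1), rarefied allelic richness and
private alleles (Hurlbert standardization), Nei's unbiased gene
diversity HE, observed heterozygosity HO, inbreeding coefficient FIS,
and pairwise Weir–Cockerham theta (FST).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as _field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "GenotypeTable", "ClonalAssignment", "find_mlgs", "assign_clones",
    "genet_dataset", "allele_counts", "pgen", "psex", "clonal_richness",
    "rarefied_allelic_richness", "rarefied_private_alleles", "diversity",
    "wc_theta", "pairwise_fst",
]


@dataclass
class GenotypeTable:
    """Ramets x loci diploid genotypes with population labels.

    ``alleles`` has shape (n_individuals, n_loci, 2) with integer
    allele codes; 0 marks a missing entry (both alleles are then 0 —
    half-missing entries are normalised to fully missing). Allele
    pairs are stored unordered-normalised (a <= b).
    """

    alleles: np.ndarray
    pops: np.ndarray
    ids: list
    loci: list

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        self.pops = np.asarray(self.pops)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, L, 2)")
        if len(self.pops) != self.alleles.shape[0] or len(self.ids) != self.alleles.shape[0]:
            raise ValueError("pops/ids length must match individuals")
        if len(self.loci) != self.alleles.shape[1]:
            raise ValueError("loci length must match")
        # both-or-neither missing, then sort pairs
        half = (self.alleles == 0).any(axis=2) & (self.alleles != 0).any(axis=2)
        self.alleles[half] = 0
        self.alleles = np.sort(self.alleles, axis=2)

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def pop_names(self) -> list:
        seen, out = set(), []
        for p in self.pops:
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def scored(self) -> np.ndarray:
        """(n, L) boolean: locus scored (non-missing) per individual."""
        return self.alleles[:, :, 0] > 0

    def subset(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(self.alleles[index].copy(), self.pops[index].copy(),
                             [self.ids[i] for i in index], list(self.loci))


@dataclass
class ClonalAssignment:
    """Partition of ramets into genets, with the Psex bookkeeping.

    ``genet_ids`` gives one integer label per ramet; ``mlg_table`` has
    one row per repeated-or-not MLG (mlg_id, pop, n, pgen, psex,
    merged); ``pop_table`` has per-population N (ramets) and G
    (genets). ``excluded`` lists ramet indices dropped for having no
    scored locus.
    """

    genet_ids: np.ndarray
    mlg_table: pd.DataFrame
    pop_table: pd.DataFrame
    excluded: list = _field(default_factory=list)
    pop_freqs: np.ndarray | None = None  # attached by simulators

    @classmethod
    def from_genet_ids(cls, table: GenotypeTable, genet_ids: np.ndarray) -> "ClonalAssignment":
        genet_ids = np.asarray(genet_ids, dtype=int)
        rows = []
        for gid in np.unique(genet_ids):
            members = np.flatnonzero(genet_ids == gid)
            rows.append((int(gid), table.pops[members[0]], len(members), np.nan, np.nan, True))
        mlg = pd.DataFrame(rows, columns=["mlg_id", "pop", "n", "pgen", "psex", "merged"])
        pop_rows = []
        for p in table.pop_names:
            m = table.pops == p
            pop_rows.append((p, int(m.sum()), len(np.unique(genet_ids[m]))))
        pops = pd.DataFrame(pop_rows, columns=["pop", "N", "G"])
        return cls(genet_ids=genet_ids, mlg_table=mlg, pop_table=pops)


# ---------------------------------------------------------------------
# MLG grouping and Psex
# ---------------------------------------------------------------------

def find_mlgs(table: GenotypeTable, max_missing_frac: float = 0.5) -> ClonalAssignment:
    """Group identical multilocus genotypes within each population.

    Two ramets share an MLG iff they match at every locus where both
    are scored and neither is missing more than ``max_missing_frac`` of
    its loci (missing entries act as wildcards on mutually scored
    loci). Grouping is greedy in input order and deterministic: a ramet
    joins the first MLG compatible with all current members. Ramets
    with no scored locus are excluded with a warning.
    """
    n, L = table.n, table.n_loci
    scored = table.scored()
    excluded = list(np.flatnonzero(~scored.any(axis=1)))
    if excluded:
        warnings.warn(f"{len(excluded)} individual(s) with no scored locus excluded")
    genet_ids = np.full(n, -1, dtype=int)
    next_id = 0
    for p in table.pop_names:
        members_of: list[list[int]] = []
        ids_of: list[int] = []
        for i in np.flatnonzero(table.pops == p):
            if i in excluded:
                continue
            hi_missing_i = (~scored[i]).mean() > max_missing_frac
            placed = False
            if not hi_missing_i:
                for mlg_members, mid in zip(members_of, ids_of):
                    ok = True
                    for j in mlg_members:
                        both = scored[i] & scored[j]
                        if (~scored[j]).mean() > max_missing_frac or not np.array_equal(
                                table.alleles[i][both], table.alleles[j][both]):
                            ok = False
                            break
                    if ok:
                        mlg_members.append(int(i))
                        genet_ids[i] = mid
                        placed = True
                        break
            if not placed:
                members_of.append([int(i)])
                ids_of.append(next_id)
                genet_ids[i] = next_id
                next_id += 1
    keep = genet_ids >= 0
    sub = table.subset(keep) if excluded else table
    ca = ClonalAssignment.from_genet_ids(sub, genet_ids[keep])
    ca.excluded = excluded
    if excluded:
        # re-express genet ids on the full table, excluded ramets = -1
        full = np.full(n, -1, dtype=int)
        full[keep] = ca.genet_ids
        ca.genet_ids = full
    return ca


def allele_counts(table: GenotypeTable) -> tuple[list, np.ndarray]:
    """Per-population per-locus allele counts (gene copies).

    Returns (pop_names, counts) with counts shaped
    (n_pops, n_loci, max_code + 1); column 0 (missing) is always zero.
    """
    amax = int(table.alleles.max())
    pops = table.pop_names
    counts = np.zeros((len(pops), table.n_loci, amax + 1), dtype=int)
    for pi, p in enumerate(pops):
        sub = table.alleles[table.pops == p]
        for l in range(table.n_loci):
            vals = sub[:, l, :].ravel()
            vals = vals[vals > 0]
            np.add.at(counts[pi, l], vals, 1)
    return pops, counts


def _freqs_from_counts(counts_1d: np.ndarray) -> np.ndarray:
    tot = counts_1d.sum()
    return counts_1d / tot if tot > 0 else counts_1d.astype(float)


def pgen(genotype: np.ndarray, freqs: np.ndarray) -> float:
    """Probability of one sexual event producing ``genotype`` under
    Hardy–Weinberg, given per-locus allele frequencies.

    ``genotype`` is (L, 2) with 0 = missing (skipped); ``freqs`` is
    (L, max_code + 1). Product over scored loci of p_a^2 for
    homozygotes and 2 p_a p_b for heterozygotes. Raises if a scored
    allele has zero frequency.
    """
    genotype = np.asarray(genotype)
    out = 1.0
    for l in range(genotype.shape[0]):
        a, b = int(genotype[l, 0]), int(genotype[l, 1])
        if a == 0:
            continue
        pa, pb = freqs[l, a], freqs[l, b]
        if pa <= 0 or pb <= 0:
            raise ValueError(f"allele {a if pa <= 0 else b} absent from frequency table at locus {l}")
        out *= pa * pb if a == b else 2.0 * pa * pb
    return out


def psex(p_gen: float, n: int, N: int, conditional: bool = False) -> float:
    """Probability that >= n copies of an MLG with per-draw probability
    ``p_gen`` arise among N samples from distinct sexual events.

    Unconditional (default): binomial upper tail
    sum_{i=n}^{N} C(N,i) p^i (1-p)^(N-i). The conditional variant
    conditions on one observed copy (n-1 extra copies among N-1).
    """
    if not 2 <= n <= N:
        raise ValueError("need 2 <= n <= N")
    if not 0.0 <= p_gen <= 1.0:
        raise ValueError("pgen must lie in [0, 1]")
    if conditional:
        return float(binom.sf(n - 2, N - 1, p_gen))
    return float(binom.sf(n - 1, N, p_gen))


def assign_clones(table: GenotypeTable, threshold: float = 0.01,
                  conditional: bool = False,
                  max_missing_frac: float = 0.5) -> ClonalAssignment:
    """Full clonal discrimination: MLG grouping, then Psex merging.

    Allele frequencies for pgen are computed from genet-level data of
    each population (one copy per distinct MLG). Repeated MLGs with
    Psex < ``threshold`` are merged into a single genet; above the
    threshold their copies are treated as independent sexual recruits
    and count as distinct genets.
    """
    ca = find_mlgs(table, max_missing_frac=max_missing_frac)
    kept = ca.genet_ids >= 0
    sub = table.subset(kept)
    ids = ca.genet_ids[kept]
    # one representative per MLG -> genet-level frequencies
    _, first_idx = np.unique(ids, return_index=True)
    uniq = sub.subset(np.sort(first_idx))
    pop_names, counts = allele_counts(uniq)
    freqs = {p: np.apply_along_axis(_freqs_from_counts, 1, counts[pi])
             for pi, p in enumerate(pop_names)}
    pop_N = {p: int((sub.pops == p).sum()) for p in pop_names}

    rows = []
    genet_out = np.full(table.n, -1, dtype=int)
    next_id = 0
    for mlg_id in np.unique(ids):
        members = np.flatnonzero(ids == mlg_id)
        pop = sub.pops[members[0]]
        ncopies = len(members)
        rep = sub.alleles[members[0]]
        if ncopies == 1:
            rows.append((int(mlg_id), pop, 1, np.nan, np.nan, False))
            genet_out[np.flatnonzero(kept)[members]] = next_id
            next_id += 1
            continue
        pg = pgen(rep, freqs[pop])
        ps = psex(pg, ncopies, pop_N[pop], conditional=conditional)
        merged = ps < threshold
        rows.append((int(mlg_id), pop, ncopies, pg, ps, bool(merged)))
        orig = np.flatnonzero(kept)[members]
        if merged:
            genet_out[orig] = next_id
            next_id += 1
        else:
            for o in orig:
                genet_out[o] = next_id
                next_id += 1
    mlg = pd.DataFrame(rows, columns=["mlg_id", "pop", "n", "pgen", "psex", "merged"])
    pop_rows = []
    for p in table.pop_names:
        m = (table.pops == p) & (genet_out >= 0)
        pop_rows.append((p, int(m.sum()), len(np.unique(genet_out[m]))))
    out = ClonalAssignment(
        genet_ids=genet_out, mlg_table=mlg,
        pop_table=pd.DataFrame(pop_rows, columns=["pop", "N", "G"]),
        excluded=ca.excluded)
    return out


def genet_dataset(table: GenotypeTable, ca: ClonalAssignment) -> GenotypeTable:
    """Collapse a ramet table to one representative ramet per genet."""
    kept = ca.genet_ids >= 0
    _, first = np.unique(ca.genet_ids[kept], return_index=True)
    idx = np.flatnonzero(kept)[np.sort(first)]
    return table.subset(idx)


def clonal_richness(N: int, G: int) -> float:
    """Clonal (genotypic) richness R = (G-1)/(N-1).

    0 for a monoclonal sample, 1 when every ramet is a distinct genet;
    NaN (undefined) for N = 1.
    """
    if N < 1 or not 1 <= G <= N:
        raise ValueError("need N >= 1 and 1 <= G <= N")
    if N == 1:
        return float("nan")
    return (G - 1) / (N - 1)


# ---------------------------------------------------------------------
# Rarefaction (Hurlbert standardization)
# ---------------------------------------------------------------------

def _hurlbert_expected(counts: np.ndarray, g: int, private_mask=None) -> float:
    """Expected number of (optionally private) alleles in a subsample
    of g gene copies drawn without replacement; exact rationals."""
    counts = np.asarray(counts, dtype=int)
    N = int(counts.sum())
    if g > N:
        raise ValueError(f"g={g} exceeds the {N} gene copies available")
    total = Fraction(0)
    for a, Na in enumerate(counts):
        if Na == 0:
            continue
        if private_mask is not None and not private_mask[a]:
            continue
        total += 1 - Fraction(math.comb(N - Na, g), math.comb(N, g))
    return float(total)


def rarefied_allelic_richness(table: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Allelic richness per population standardized to g gene copies.

    Default g = 2 x the minimum genet sample size over populations.
    Returns per-population Â (mean over loci) and per-locus detail
    columns. Raises if any population has fewer than g copies scored
    at some locus.
    """
    pops, counts = allele_counts(table)
    copies = counts.sum(axis=2)  # (P, L)
    if g is None:
        g = int(2 * min(np.sum(table.pops == p) for p in pops))
    rows = []
    for pi, p in enumerate(pops):
        per_locus = [_hurlbert_expected(counts[pi, l], g) for l in range(table.n_loci)]
        rows.append([p, g, float(np.mean(per_locus))] + per_locus)
    cols = ["pop", "g", "A_hat"] + [f"A_{l}" for l in table.loci]
    return pd.DataFrame(rows, columns=cols)


def rarefied_private_alleles(table: GenotypeTable, g: int | None = None) -> pd.DataFrame:
    """Rarefied count of private alleles (absent from every other
    population's full sample), standardized to g copies; PÂ is the
    mean over loci."""
    pops, counts = allele_counts(table)
    if g is None:
        g = int(2 * min(np.sum(table.pops == p) for p in pops))
    rows = []
    for pi, p in enumerate(pops):
        per_locus = []
        for l in range(table.n_loci):
            others = counts[:, l, :].sum(axis=0) - counts[pi, l, :]
            private = (others == 0) & (counts[pi, l, :] > 0)
            per_locus.append(_hurlbert_expected(counts[pi, l], g, private_mask=private))
        rows.append([p, g, float(np.mean(per_locus))] + per_locus)
    cols = ["pop", "g", "PA_hat"] + [f"PA_{l}" for l in table.loci]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------
# Diversity and differentiation
# ---------------------------------------------------------------------

def diversity(table: GenotypeTable) -> dict:
    """HO, Nei-unbiased HE and FIS, per locus and multilocus.

    Per locus: HO = fraction heterozygous among scored individuals;
    HE = (ñ/(ñ-1)) (1 - sum p_k^2) with ñ the scored gene copies;
    FIS = 1 - HO/HE (NaN at monomorphic loci, where HE = 0).
    Multilocus FIS = 1 - mean(HO)/mean(HE) over loci.

    Returns {"per_locus": DataFrame, "per_pop": DataFrame}.
    """
    pops, counts = allele_counts(table)
    scored = table.scored()
    per_locus_rows, per_pop_rows = [], []
    for pi, p in enumerate(pops):
        m = table.pops == p
        if (np.unique(table.alleles[m][scored[m].any(axis=1)], axis=0).shape[0]) < 1:
            continue
        hos, hes = [], []
        for l in range(table.n_loci):
            sm = m & scored[:, l]
            n_ind = int(sm.sum())
            if n_ind == 0:
                per_locus_rows.append((p, table.loci[l], 0, np.nan, np.nan, np.nan))
                hos.append(np.nan)
                hes.append(np.nan)
                continue
            geno = table.alleles[sm, l, :]
            ho = float((geno[:, 0] != geno[:, 1]).mean())
            freq = _freqs_from_counts(counts[pi, l])
            ncop = int(counts[pi, l].sum())
            he = 0.0 if ncop < 2 else (ncop / (ncop - 1)) * (1.0 - float(np.sum(freq ** 2)))
            fis = np.nan if he == 0 else 1.0 - ho / he
            per_locus_rows.append((p, table.loci[l], n_ind, ho, he, fis))
            hos.append(ho)
            hes.append(he)
        ho_bar = float(np.nanmean(hos))
        he_bar = float(np.nanmean(hes))
        fis_multi = np.nan if he_bar == 0 else 1.0 - ho_bar / he_bar
        per_pop_rows.append((p, int(m.sum()), ho_bar, he_bar, fis_multi))
    return {
        "per_locus": pd.DataFrame(per_locus_rows,
                                  columns=["pop", "locus", "n", "HO", "HE", "FIS"]),
        "per_pop": pd.DataFrame(per_pop_rows,
                                columns=["pop", "N", "HO", "HE", "FIS"]),
    }


def wc_theta(table: GenotypeTable, pops: list | None = None,
             return_components: bool = False):
    """Weir–Cockerham theta over the given populations (all by default).

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are accumulated per
    locus per allele with sample sizes taken per locus (missing data
    allowed); theta = sum(a) / sum(a+b+c). Negative estimates are
    reported as computed. Returns NaN when the denominator is zero
    (no variation among the populations at any locus).
    """
    names = pops if pops is not None else table.pop_names
    r = len(names)
    if r < 2:
        raise ValueError("need >= 2 populations")
    masks = [table.pops == p for p in names]
    scored = table.scored()
    A_sum = B_sum = C_sum = 0.0
    per_locus = []
    for l in range(table.n_loci):
        ni = np.array([int((m & scored[:, l]).sum()) for m in masks], dtype=float)
        if np.any(ni < 1) or ni.sum() < 2:
            per_locus.append((table.loci[l], np.nan, np.nan, np.nan))
            continue
        nbar = ni.mean()
        if nbar <= 1:
            per_locus.append((table.loci[l], np.nan, np.nan, np.nan))
            continue
        nc = (r * nbar - np.sum(ni ** 2) / (r * nbar)) / (r - 1)
        alleles_here = np.unique(table.alleles[:, l, :][table.alleles[:, l, :] > 0])
        la = lb = lc = 0.0
        for a in alleles_here:
            p_i = np.empty(r)
            h_i = np.empty(r)
            for k, m in enumerate(masks):
                sm = m & scored[:, l]
                geno = table.alleles[sm, l, :]
                p_i[k] = float((geno == a).sum()) / (2.0 * ni[k])
                h_i[k] = float(((geno == a).sum(axis=1) == 1).mean())
            pbar = float(np.sum(ni * p_i) / (r * nbar))
            s2 = float(np.sum(ni * (p_i - pbar) ** 2) / ((r - 1) * nbar))
            hbar = float(np.sum(ni * h_i) / (r * nbar))
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            aa = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
            bb = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            cc = hbar / 2.0
            la += aa
            lb += bb
            lc += cc
        A_sum += la
        B_sum += lb
        C_sum += lc
        per_locus.append((table.loci[l], la, lb, lc))
    denom = A_sum + B_sum + C_sum
    theta = np.nan if denom == 0 else A_sum / denom
    if return_components:
        return theta, pd.DataFrame(per_locus, columns=["locus", "a", "b", "c"])
    return theta


@dataclass
class FstMatrix:
    pops: list
    theta: np.ndarray  # symmetric, diagonal 0, NaN where undefined

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.pops, columns=self.pops)

    def linearized(self) -> np.ndarray:
        """theta / (1 - theta), the standard linearization for
        distance-matrix comparisons."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.theta / (1.0 - self.theta)


def pairwise_fst(table: GenotypeTable) -> FstMatrix:
    """Pairwise multilocus Weir–Cockerham theta between populations.

    Pairs where theta is undefined (no shared polymorphism) carry NaN.
    """
    names = table.pop_names
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    th = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t = wc_theta(table, pops=[names[i], names[j]])
            th[i, j] = th[j, i] = t
    return FstMatrix(pops=names, theta=th)
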