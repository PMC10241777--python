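"""Synthetic study systems with known ground truth.

Three generators stand in for inputs that real studies download or
collect: analytic daily current fields with land masks (in place of an
eddy-resolving hindcast), clustered species occurrence records, and
clonal multilocus microsatellite genotypes with controllable
population differentiation, clonality and missing data.

All randomness flows from a single top-level seed, split per generator
with :class:`numpy.random.SeedSequence`, so every fixture is exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd

from .advection import VelocityField
from .geo import KM_PER_DEG, local_xy_m
from .popgen import GenotypeTable, ClonalAssignment

FIELD_KINDS = ("zero", "uniform", "solid_rotation", "double_gyre")


@dataclass
class FieldSpec:
    """Recipe for an analytic velocity field.

    ``amplitude`` is the characteristic speed in m/s (the maximum zonal
    speed for the double gyre; the uniform speed for ``uniform``). For
    ``solid_rotation``, ``omega`` (rad/s) takes precedence when given,
    otherwise the angular rate is chosen so the speed at the farthest
    domain corner equals ``amplitude``.
    """

    kind: str = "double_gyre"
    lon_min: float = -40.0
    lon_max: float = -30.0
    lat_min: float = 0.0
    lat_max: float = 10.0
    step_deg: float = 0.25
    n_days: int = 1
    amplitude: float = 0.1
    center: tuple[float, float] | None = None
    omega: float | None = None
    start_date: str = "2008-01-01"
    land_border: int = 0  # nodes of land framing the domain edge
    #: time-dependent gyre driving (0 = steady); the classic periodically
    #: perturbed double gyre, with the separatrix swinging by ~gyre_eps
    gyre_eps: float = 0.0
    gyre_period_days: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.step_deg <= 0:
            raise ValueError("grid step must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("bounds must define a non-empty rectangle")


def make_velocity_field(spec: FieldSpec) -> VelocityField:
    """Build the analytic field described by ``spec``.

    The double gyre derives u, v from a stream function by central
    differences on the grid, so its central-difference divergence
    vanishes identically at interior nodes (mixed discrete partials
    commute).
    """
    lon = np.arange(spec.lon_min, spec.lon_max + spec.step_deg / 2, spec.step_deg)
    lat = np.arange(spec.lat_min, spec.lat_max + spec.step_deg / 2, spec.step_deg)
    LON, LAT = np.meshgrid(lon, lat)
    cx = spec.center[0] if spec.center else (spec.lon_min + spec.lon_max) / 2
    cy = spec.center[1] if spec.center else (spec.lat_min + spec.lat_max) / 2
    x, y = local_xy_m(LON, LAT, cx, cy)  # metres about the centre

    if spec.kind == "zero":
        u = np.zeros_like(LON)
        v = np.zeros_like(LON)
    elif spec.kind == "uniform":
        u = np.full_like(LON, spec.amplitude)
        v = np.zeros_like(LON)
    elif spec.kind == "solid_rotation":
        rmax = float(np.max(np.hypot(x, y)))
        omega = spec.omega if spec.omega is not None else spec.amplitude / rmax
        u = -omega * y
        v = omega * x
    else:  # double_gyre
        x0, y0 = local_xy_m(spec.lon_min, spec.lat_min, cx, cy)
        x1, y1 = local_xy_m(spec.lon_max, spec.lat_max, cx, cy)
        X = (x - x0) / (x1 - x0) * 2.0  # [0, 2]
        Y = (y - y0) / (y1 - y0)        # [0, 1]
        A = spec.amplitude * (y1 - y0) / np.pi

        def gyre_uv(day: int):
            if spec.gyre_eps > 0:
                e = spec.gyre_eps * np.sin(2 * np.pi * day / spec.gyre_period_days)
                fX = e * X ** 2 + (1.0 - 2.0 * e) * X
            else:
                fX = X
            psi = A * np.sin(np.pi * fX) * np.sin(np.pi * Y)
            return -_ddy(psi, y), _ddx(psi, x)

        u, v = gyre_uv(0)

    land = np.zeros(LON.shape, dtype=bool)
    if spec.land_border > 0:
        b = spec.land_border
        land[:b, :] = land[-b:, :] = True
        land[:, :b] = land[:, -b:] = True

    dates = np.datetime64(spec.start_date, "D") + np.arange(spec.n_days).astype("timedelta64[D]")
    if spec.kind == "double_gyre" and spec.gyre_eps > 0:
        U = np.empty((spec.n_days,) + u.shape)
        V = np.empty_like(U)
        for d in range(spec.n_days):
            U[d], V[d] = gyre_uv(d)
    else:
        U = np.broadcast_to(u, (spec.n_days,) + u.shape).copy()
        V = np.broadcast_to(v, (spec.n_days,) + v.shape).copy()
    U[:, land] = 0.0
    V[:, land] = 0.0
    return VelocityField(lon=lon, lat=lat, dates=dates, u=U, v=V, land=land)


def _ddx(f: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Central differences along axis 1, one-sided at the edges."""
    g = np.empty_like(f)
    g[:, 1:-1] = (f[:, 2:] - f[:, :-2]) / (x[:, 2:] - x[:, :-2])
    g[:, 0] = (f[:, 1] - f[:, 0]) / (x[:, 1] - x[:, 0])
    g[:, -1] = (f[:, -1] - f[:, -2]) / (x[:, -1] - x[:, -2])
    return g


def _ddy(f: np.ndarray, y: np.ndarray) -> np.ndarray:
    g = np.empty_like(f)
    g[1:-1, :] = (f[2:, :] - f[:-2, :]) / (y[2:, :] - y[:-2, :])
    g[0, :] = (f[1, :] - f[0, :]) / (y[1, :] - y[0, :])
    g[-1, :] = (f[-1, :] - f[-2, :]) / (y[-1, :] - y[-2, :])
    return g


def make_occurrences(site_centers, n_per_center: int, jitter_km: float, seed: int,
                     field: VelocityField | None = None) -> pd.DataFrame:
    """Clustered occurrence records around known centres.

    Jitter is isotropic Gaussian with SD ``jitter_km``, truncated at
    3 SD by resampling, so every record lies within 3 x jitter of its
    centre. When a ``field`` is given, centres on land are rejected.
    Deterministic under a fixed seed.
    """
    centers = [(float(a), float(b)) for a, b in site_centers]
    if field is not None:
        bad = [c for c in centers if bool(field.is_land(c[0], c[1]))]
        if bad:
            raise ValueError(f"centers on land: {bad}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for k, (clon, clat) in enumerate(centers):
        dx = _truncated_normal(rng, n_per_center, 3.0) * jitter_km
        dy = _truncated_normal(rng, n_per_center, 3.0) * jitter_km
        lat = clat + dy / KM_PER_DEG
        lon = clon + dx / (KM_PER_DEG * math.cos(math.radians(clat)))
        for i in range(n_per_center):
            rows.append((lon[i], lat[i], f"center_{k}"))
    return pd.DataFrame(rows, columns=["lon", "lat", "source"])


def _truncated_normal(rng: np.random.Generator, n: int, bound: float) -> np.ndarray:
    out = rng.standard_normal(n)
    while True:
        bad = np.abs(out) > bound
        if not bad.any():
            return out
        out[bad] = rng.standard_normal(int(bad.sum()))


@dataclass
class GenoSimSpec:
    """Recipe for a clonal multilocus genotype sample.

    ``differentiation`` is a single knob in [0, 1] for among-population
    allele-frequency spread: per-population frequencies are drawn from
    a Dirichlet centred on a global frequency vector with concentration
    (1-d)/d (an island-model beta spread); d=0 copies the global
    frequencies, d=1 fixes a single allele per population.

    ``clonality`` is the probability that a sampled ramet is a copy of
    an already-resident genet rather than a fresh sexual recruit. The
    number of distinct founder genets is capped at ``genets_per_pop``.
    """

    n_pops: int = 19
    genets_per_pop: int = 10
    ramets_per_pop: int = 25
    n_loci: int = 8
    alleles_per_locus: int = 6
    differentiation: float = 0.1
    clonality: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ramets_per_pop >= self.genets_per_pop >= 1):
            raise ValueError("need ramets_per_pop >= genets_per_pop >= 1")
        for name in ("differentiation", "clonality", "missing_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_pops < 1 or self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ValueError("counts must be >= 1")


def make_genotypes(spec: GenoSimSpec) -> tuple[GenotypeTable, ClonalAssignment]:
    """Simulate ramet genotypes plus the ground-truth clonal partition.

    Sampling is a sequential urn per population: the first ramet founds
    a genet (two alleles per locus drawn from the population's
    frequencies); each later ramet is, with probability ``clonality``,
    an exact copy of a uniformly chosen resident genet, and otherwise a
    fresh genet draw — until ``genets_per_pop`` founders exist, after
    which all further ramets are copies. clonality=1 therefore yields a
    single clone per population (R = 0) and clonality=0 with
    genets_per_pop = ramets_per_pop yields all-distinct draws.

    Missing data: each (ramet, locus) entry is blanked (both alleles 0)
    independently with probability ``missing_rate``.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_freq = np.random.default_rng(ss[0])
    rng_geno = np.random.default_rng(ss[1])
    rng_miss = np.random.default_rng(ss[2])

    L, K = spec.n_loci, spec.alleles_per_locus
    global_freqs = rng_freq.dirichlet(np.ones(K), size=L)  # (L, K)
    pop_freqs = np.empty((spec.n_pops, L, K))
    d = spec.differentiation
    for p in range(spec.n_pops):
        for l in range(L):
            if d == 0.0:
                pop_freqs[p, l] = global_freqs[l]
            elif d == 1.0:
                a = rng_freq.choice(K, p=global_freqs[l])
                pop_freqs[p, l] = np.eye(K)[a]
            else:
                conc = (1.0 - d) / d
                pop_freqs[p, l] = rng_freq.dirichlet(global_freqs[l] * conc)

    table, truth = _sample_clonal_ramets(pop_freqs, spec, rng_geno, rng_miss)
    return table, truth


def make_genotypes_chain(spec: GenoSimSpec, drift: float = 0.1) -> tuple[GenotypeTable, ClonalAssignment]:
    """Genotypes with stepping-stone (isolation-by-distance) structure.

    Populations sit on a chain; each population's allele frequencies
    are a Dirichlet perturbation of its neighbour's, with concentration
    (1-drift)/drift per step, so differentiation accumulates with chain
    distance — the genetic pattern expected when gene flow follows a
    linear dispersal corridor. ``spec.differentiation`` is ignored;
    ``drift`` in (0, 1) sets the per-step spread.
    """
    if not 0.0 < drift < 1.0:
        raise ValueError("drift must lie in (0, 1)")
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_freq = np.random.default_rng(ss[0])
    rng_geno = np.random.default_rng(ss[1])
    rng_miss = np.random.default_rng(ss[2])
    L, K = spec.n_loci, spec.alleles_per_locus
    conc = (1.0 - drift) / drift
    pop_freqs = np.empty((spec.n_pops, L, K))
    for l in range(L):
        pop_freqs[0, l] = rng_freq.dirichlet(np.full(K, 2.0))
        for p in range(1, spec.n_pops):
            alpha = np.maximum(pop_freqs[p - 1, l] * conc, 1e-3)
            pop_freqs[p, l] = rng_freq.dirichlet(alpha)
    return _sample_clonal_ramets(pop_freqs, spec, rng_geno, rng_miss)


def make_genotypes_from_distance(D: np.ndarray, spec: GenoSimSpec,
                                 scale: float | None = None,
                                 sigma: float = 1.0) -> tuple[GenotypeTable, ClonalAssignment]:
    """Genotypes whose differentiation tracks a supplied dispersal-cost
    matrix — gene flow "following" a modelled connectivity field.

    ``D`` is a symmetric (n_pops x n_pops) cost/distance matrix (e.g.
    -log stepping-stone probability, or km). Per locus and allele,
    logit-scale perturbations are drawn from a Gaussian process with
    covariance sigma^2 * exp(-D/scale) (scale defaults to the median
    off-diagonal cost), so nearby populations share correlated
    frequencies and differentiation accumulates with cost. Clonality
    and missing data then follow ``spec`` as in :func:`make_genotypes`.
    """
    D = np.asarray(D, dtype=float)
    n = spec.n_pops
    if D.shape != (n, n):
        raise ValueError("D must be (n_pops, n_pops)")
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng_freq = np.random.default_rng(ss[0])
    rng_geno = np.random.default_rng(ss[1])
    rng_miss = np.random.default_rng(ss[2])
    if scale is None:
        off = D[~np.eye(n, dtype=bool)]
        finite = off[np.isfinite(off) & (off > 0)]
        scale = float(np.median(finite)) if len(finite) else 1.0
    Dcap = np.where(np.isfinite(D), D, D[np.isfinite(D)].max() * 10 if np.isfinite(D).any() else 1.0)
    cov = sigma ** 2 * np.exp(-Dcap / scale)
    cov = (cov + cov.T) / 2.0
    # an arbitrary cost matrix need not yield a PSD kernel: clip spectrum
    w, V = np.linalg.eigh(cov)
    chol = V * np.sqrt(np.maximum(w, 0.0))[None, :]
    L, K = spec.n_loci, spec.alleles_per_locus
    pop_freqs = np.empty((n, L, K))
    for l in range(L):
        base = np.log(rng_freq.dirichlet(np.full(K, 2.0)))
        z = chol @ rng_freq.standard_normal((n, K))  # correlated over pops
        logits = base[None, :] + z
        expl = np.exp(logits - logits.max(axis=1, keepdims=True))
        pop_freqs[:, l, :] = expl / expl.sum(axis=1, keepdims=True)
    return _sample_clonal_ramets(pop_freqs, spec, rng_geno, rng_miss)


def _sample_clonal_ramets(pop_freqs: np.ndarray, spec: GenoSimSpec,
                          rng_geno: np.random.Generator,
                          rng_miss: np.random.Generator) -> tuple[GenotypeTable, ClonalAssignment]:
    L, K = spec.n_loci, spec.alleles_per_locus
    n = spec.n_pops * spec.ramets_per_pop
    alleles = np.zeros((n, L, 2), dtype=np.int16)
    pops, genet_ids = [], np.empty(n, dtype=int)
    next_genet = 0
    row = 0
    for p in range(spec.n_pops):
        pname = f"pop_{p:02d}"
        founders: list[tuple[int, np.ndarray]] = []  # (genet id, (L,2) genotype)
        for _ in range(spec.ramets_per_pop):
            fresh = (not founders) or (
                rng_geno.random() >= spec.clonality and len(founders) < spec.genets_per_pop
            )
            if fresh:
                g = np.empty((L, 2), dtype=np.int16)
                for l in range(L):
                    # allele codes are 1-based; 0 is reserved for missing
                    g[l] = np.sort(rng_geno.choice(K, size=2, p=pop_freqs[p, l]) + 1)
                founders.append((next_genet, g))
                gid, geno = next_genet, g
                next_genet += 1
            else:
                gid, geno = founders[rng_geno.integers(len(founders))]
            alleles[row] = geno
            genet_ids[row] = gid
            pops.append(pname)
            row += 1
    if spec.missing_rate > 0:
        blank = rng_miss.random((n, L)) < spec.missing_rate
        alleles[blank] = 0

    table = GenotypeTable(
        alleles=alleles,
        pops=np.array(pops),
        ids=[f"ind_{i:04d}" for i in range(n)],
        loci=[f"locus_{l + 1}" for l in range(L)],
    )
    truth = ClonalAssignment.from_genet_ids(table, genet_ids)
    truth.pop_freqs = pop_freqs  # realized simulation frequencies, for oracles
    return table, truth
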