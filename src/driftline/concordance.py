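"""Compare genetic differentiation with modelled oceanographic
connectivity (or geographic distance) across matched populations.

Genotyped populations are mapped to their nearest simulation sites;
the directional stepping-stone matrix is symmetrised (FST is not
directional); pairs the simulation finds unreachable are excluded via
a mask rather than imputed; and a Mantel permutation test correlates
linearized FST, theta/(1-theta), against -log stepping-stone
probability or great-circle distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km
from .network import SteppingStoneMatrix


def site_to_population_map(sites, pops: pd.DataFrame, max_km: float) -> pd.DataFrame:
    """Assign each genotyped population (columns pop, lon, lat) to its
    nearest simulation site; raises naming any population farther than
    ``max_km`` from every site."""
    slon = sites.table["lon"].to_numpy()
    slat = sites.table["lat"].to_numpy()
    sids = sites.table["site_id"].to_numpy()
    rows, too_far = [], []
    for _, row in pops.iterrows():
        d = haversine_km(row["lon"], row["lat"], slon, slat)
        k = int(np.argmin(d))
        if d[k] > max_km:
            too_far.append(str(row["pop"]))
        rows.append((row["pop"], int(sids[k]), float(d[k])))
    if too_far:
        raise ValueError(f"population(s) farther than {max_km} km from any site: {too_far}")
    return pd.DataFrame(rows, columns=["pop", "site_id", "distance_km"])


def symmetrize_connectivity(ss: SteppingStoneMatrix | np.ndarray,
                            mode: str = "max") -> np.ndarray:
    """Element-wise max (default) or mean of SS_ij and SS_ji."""
    m = ss.ss if isinstance(ss, SteppingStoneMatrix) else np.asarray(ss, dtype=float)
    if mode == "max":
        return np.maximum(m, m.T)
    if mode == "mean":
        return (m + m.T) / 2.0
    raise ValueError("mode must be 'max' or 'mean'")


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_pops: int
    n_pairs_used: int
    n_pairs_masked: int
    seed: int
    defined: bool = True

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def mantel(A: np.ndarray, B: np.ndarray, n_perm: int = 9999, seed: int = 0,
           mask: np.ndarray | None = None) -> MantelResult:
    """Mantel permutation test between two matched square matrices.

    Pearson r over the (optionally masked) upper-triangle entries;
    the null distribution permutes rows and columns of B
    simultaneously, keeping the mask fixed in the index frame of A.
    Two-sided p = (1 + #{|r*| >= |r|}) / (1 + n_perm). Requires at
    least 4 populations after masking; a zero-variance input returns
    an undefined (NaN) result with ``defined=False``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or B.shape != (n, n):
        raise ValueError("matrices must be square and matched")
    iu, ju = np.triu_indices(n, k=1)
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)[iu, ju]
        iu, ju = iu[keep], ju[keep]
    used_pops = np.unique(np.concatenate([iu, ju]))
    if len(used_pops) < 4:
        raise ValueError("need >= 4 populations after masking")
    a = A[iu, ju]
    b = B[iu, ju]
    if a.std() == 0 or b.std() == 0:
        return MantelResult(r=float("nan"), p=float("nan"), n_perm=n_perm,
                            n_pops=n, n_pairs_used=len(a),
                            n_pairs_masked=n * (n - 1) // 2 - len(a),
                            seed=seed, defined=False)
    r_obs = _pearson(a, b)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    bp = B[perms[:, iu], perms[:, ju]]  # (n_perm, n_pairs)
    ac = a - a.mean()
    bc = bp - bp.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac @ ac) * (bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (bc @ ac) / denom
    r_perm = np.where(denom > 0, r_perm, np.inf)  # degenerate perms count as extreme
    hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-15))
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=float(r_obs), p=float(p), n_perm=n_perm, n_pops=n,
                        n_pairs_used=len(a),
                        n_pairs_masked=n * (n - 1) // 2 - len(a), seed=seed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def neglog_ss(sym_ss: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """-log of a symmetrised stepping-stone matrix plus the mask of
    finite (reachable) pairs; the transform is floored at 0."""
    with np.errstate(divide="ignore"):
        out = -np.log(sym_ss)
    out = np.where(sym_ss > 0, np.maximum(out, 0.0), np.inf)
    return out, sym_ss > 0
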