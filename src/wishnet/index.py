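"""Aggregate genetic index from multi-trait breeding values.

Selection-index theory: given the phenotypic covariance matrix P, genetic
covariance matrix G and a vector of biological weights v over m traits, the
index coefficients are b = P^-1 G v and each animal's index is I = b'x over
its breeding values x.  Here the index is an Obesity Index: the default
weights put most emphasis on the fat-depot traits.

The coefficients are obtained by solving P b = G v (never by forming the
explicit inverse); G is only required to be symmetric — estimated genetic
covariance matrices are sometimes indefinite, which triggers a warning,
not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .simdata import DEFAULT_WEIGHTS  # noqa: F401  (re-exported default profile)

__all__ = ["SelectionIndexSpec", "IndexCoefficients", "index_coefficients",
           "obesity_index", "select_extremes", "DEFAULT_WEIGHTS"]


@dataclass(frozen=True)
class SelectionIndexSpec:
    """Trait names with P, G and biological weights v, in trait order."""

    traits: tuple
    P: np.ndarray
    G: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        traits = tuple(self.traits)
        P = np.asarray(self.P, dtype=float)
        G = np.asarray(self.G, dtype=float)
        v = np.asarray(self.v, dtype=float).ravel()
        m = len(traits)
        if len(set(traits)) != m:
            raise ValueError("trait names must be unique")
        if P.shape != (m, m) or G.shape != (m, m) or v.shape != (m,):
            raise ValueError("P, G and v dimensions must match the trait list")
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("P must be symmetric")
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("P must be positive definite")
        if np.linalg.eigvalsh(G).min() < 0:
            warnings.warn("G has negative eigenvalues (indefinite genetic "
                          "covariance estimate)", stacklevel=2)
        object.__setattr__(self, "traits", traits)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "v", v)


@dataclass(frozen=True)
class IndexCoefficients:
    traits: tuple
    b: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float).ravel()
        if len(b) != len(self.traits):
            raise ValueError("coefficient vector does not match trait list")
        if not np.all(np.isfinite(b)):
            raise ValueError("index coefficients must be finite")
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "b", b)

    def as_series(self) -> pd.Series:
        return pd.Series(self.b, index=list(self.traits), name="b")


def index_coefficients(spec: SelectionIndexSpec,
                       max_condition: float = 1e12) -> IndexCoefficients:
    """Solve P b = G v for the index coefficients.

    Raises if P is numerically singular (condition number above
    ``max_condition``), reporting the smallest eigenvalue.
    """
    w = np.linalg.eigvalsh(spec.P)
    if w.min() <= 0 or w.max() / w.min() > max_condition:
        raise np.linalg.LinAlgError(
            f"P is singular or ill-conditioned (smallest eigenvalue "
            f"{w.min():.3e}, condition number {w.max() / max(w.min(), 1e-300):.3e})"
        )
    rhs = spec.G @ spec.v
    b = linalg.solve(spec.P, rhs, assume_a="sym")
    resid = np.abs(spec.P @ b - rhs).max()
    scale = max(np.abs(rhs).max(), 1e-300)
    if resid > 1e-8 * scale:
        raise np.linalg.LinAlgError(
            f"linear solve did not converge: ||Pb - Gv||_inf = {resid:.3e}"
        )
    return IndexCoefficients(spec.traits, b)


def obesity_index(coef: IndexCoefficients, ebvs: pd.DataFrame,
                  ebv_suffix: str = "_ebv", standardize: bool = False,
                  ) -> tuple[pd.Series, list]:
    """Per-animal index I = b'x from a breeding-value table.

    ``ebvs`` must be indexed by animal id (or carry an ``animal_id`` column)
    with one column per index trait, either bare or suffixed.  Animals with
    any missing index-trait value are omitted and returned in a list.
    Standardization (z-scaling of the index) is off by default: the index is
    reported in its natural units.
    """
    df = ebvs
    if "animal_id" in df.columns:
        df = df.set_index("animal_id")
    cols = {}
    for t in coef.traits:
        if f"{t}{ebv_suffix}" in df.columns:
            cols[t] = f"{t}{ebv_suffix}"
        elif t in df.columns:
            cols[t] = t
    if not cols:
        raise ValueError("no overlap between index traits and EBV columns")
    missing_traits = [t for t in coef.traits if t not in cols]
    if missing_traits:
        raise ValueError(f"EBV table lacks index traits: {missing_traits}")
    x = df[[cols[t] for t in coef.traits]].astype(float)
    complete = x.notna().all(axis=1)
    omitted = x.index[~complete].tolist()
    oi = pd.Series(x[complete].to_numpy() @ coef.b,
                   index=x.index[complete], name="OI")
    if standardize:
        oi = (oi - oi.mean()) / oi.std(ddof=1)
    return oi, omitted


def select_extremes(oi: pd.Series, scheme: dict) -> dict:
    """Index-extreme animal subsets.

    ``scheme`` maps group names to counts; recognized groups are ``low``
    (smallest index values), ``high`` (largest), ``mid`` (closest to the
    cohort median among animals not already taken), and the aliases
    ``lean`` -> low, ``obese`` -> high.  Subsets are disjoint; ties are
    broken by animal id so that the selection does not depend on input
    order.
    """
    alias = {"lean": "low", "obese": "high"}
    norm = {}
    for k, n in scheme.items():
        key = alias.get(k, k)
        if key not in ("low", "mid", "high"):
            raise ValueError(f"unknown selection group {k!r}")
        if key in norm:
            raise ValueError(f"duplicate selection group {key!r}")
        norm[key] = int(n)
    if sum(norm.values()) > len(oi):
        raise ValueError(
            f"requested {sum(norm.values())} animals from a cohort of {len(oi)}"
        )
    # deterministic order: sort by (value, id)
    s = oi.copy()
    s = s.iloc[np.lexsort((np.asarray(s.index, dtype=object), s.to_numpy()))]
    out = {}
    taken: set = set()
    if "low" in norm:
        ids = [a for a in s.index if a not in taken][: norm["low"]]
        out[_orig_key(scheme, "low")] = list(ids)
        taken |= set(ids)
    if "high" in norm:
        ids = [a for a in s.index[::-1] if a not in taken][: norm["high"]]
        out[_orig_key(scheme, "high")] = list(ids)[::-1]
        taken |= set(ids)
    if "mid" in norm:
        med = float(oi.median())
        dist = (s - med).abs()
        order = dist.iloc[
            np.lexsort((np.asarray(dist.index, dtype=object), dist.to_numpy()))
        ]
        ids = [a for a in order.index if a not in taken][: norm["mid"]]
        out[_orig_key(scheme, "mid")] = list(ids)
        taken |= set(ids)
    for k, ids in out.items():
        if len(ids) != norm[{"lean": "low", "obese": "high"}.get(k, k)]:
            raise ValueError(f"could not fill selection group {k!r}")
    return out


def _orig_key(scheme: dict, canonical: str) -> str:
    alias = {"lean": "low", "obese": "high"}
    for k in scheme:
        if alias.get(k, k) == canonical:
            return k
    return canonical
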