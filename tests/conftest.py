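"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: relationship
entries come from Monte-Carlo gene dropping, BLUP solutions from the dense
V-based GLS equations, HWE p-values from exact rational enumeration, and
REML optima from a likelihood grid search on the variance-ratio scale.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from sibstep import Pedigree, read_pedigree


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


@pytest.fixture
def fullsib_pedigree() -> Pedigree:
    """Two unrelated, non-inbred founders with two joint offspring."""
    return read_pedigree([("O1", "S", "D"), ("O2", "S", "D")])


@pytest.fixture
def inbred_pedigree() -> Pedigree:
    """Three-generation pedigree with a full-sib mating (F of E = 0.25)."""
    return read_pedigree([("C", "A", "B"), ("D", "A", "B"), ("E", "C", "D")])


def random_pedigree_records(rng: np.random.Generator, n: int = 12, p_founder: float = 0.35):
    """Random valid pedigree records; parents always precede offspring."""
    records = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            records.append((f"A{i}", "0", "0"))
        else:
            s = int(rng.integers(0, i))
            d = int(rng.integers(0, i))
            records.append((f"A{i}", f"A{s}", f"A{d}" if d != s else "0"))
    return records


# ---------------------------------------------------------------------------
# Monte-Carlo IBD oracle
# ---------------------------------------------------------------------------


def ibd_relationship_mc(ped: Pedigree, n_rep: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """Additive-relationship matrix estimated by gene dropping.

    Founders receive unique allele labels; each replicate drops alleles down
    the pedigree independently.  ``a_ij`` is estimated as half the expected
    count of IBD matches among the four cross-animal allele comparisons,
    and ``a_ii`` as ``1 + P(the two alleles of i are IBD)``.
    """
    rng = np.random.default_rng(seed)
    n = ped.n
    alleles = np.empty((n, 2, n_rep), dtype=np.int16)
    for i in range(n):
        for which, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
            if parent == 0:
                alleles[i, which, :] = 2 * i + which
            else:
                pick = rng.integers(0, 2, size=n_rep)
                alleles[i, which, :] = np.where(
                    pick == 0, alleles[parent - 1, 0, :], alleles[parent - 1, 1, :]
                )
    a = np.empty((n, n))
    for i in range(n):
        a[i, i] = 1.0 + np.mean(alleles[i, 0, :] == alleles[i, 1, :])
        for j in range(i):
            matches = sum(
                np.mean(alleles[i, k, :] == alleles[j, m, :])
                for k in (0, 1)
                for m in (0, 1)
            )
            a[i, j] = a[j, i] = matches / 2.0
    return a


# ---------------------------------------------------------------------------
# dense V-based GLS/BLUP oracle
# ---------------------------------------------------------------------------


def gls_blup_oracle(y, X, Z, Gmat, sigma_a2, sigma_e2):
    """BLUP via Var(y) = Z G Z' sigma_a2 + I sigma_e2, no MME involved.

    Returns (beta_hat, u_hat, pev) with pev = diag Var(u - u_hat).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.asarray(Z, float)
    Gu = np.asarray(Gmat, float) * sigma_a2
    V = Z @ Gu @ Z.T + np.eye(len(y)) * sigma_e2
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ beta
    u = Gu @ Z.T @ Vi @ resid
    P = Vi - Vi @ X @ np.linalg.inv(XtVi @ X) @ XtVi
    pev = np.diag(Gu - Gu @ Z.T @ P @ Z @ Gu)
    return beta, u, pev


# ---------------------------------------------------------------------------
# HWE exact enumeration oracle (rational arithmetic)
# ---------------------------------------------------------------------------


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-test p-value via Fraction enumeration over heterozygote counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    probs = {}
    total = Fraction(0)
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        w = Fraction(2**h) * Fraction(
            math.factorial(n), math.factorial(hr) * math.factorial(h) * math.factorial(hc)
        )
        probs[h] = w
        total += w
    p_obs = probs[n_het]
    return float(sum(w for w in probs.values() if w <= p_obs) / total)


# ---------------------------------------------------------------------------
# REML likelihood grid oracle
# ---------------------------------------------------------------------------


def reml_profile_loglik(y, X, S, h2: float) -> float:
    """Restricted log-likelihood profiled over total variance at fixed h2."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    V0 = h2 * np.asarray(S, float) + (1.0 - h2) * np.eye(n)
    V0i = np.linalg.inv(V0)
    XtVi = X.T @ V0i
    M = XtVi @ X
    beta = np.linalg.solve(M, XtVi @ y)
    r = y - X @ beta
    quad = float(r @ V0i @ r)
    sp2 = quad / (n - p)
    s1, ld_v = np.linalg.slogdet(V0)
    s2, ld_m = np.linalg.slogdet(M)
    if s1 <= 0 or s2 <= 0 or sp2 <= 0:
        return -np.inf
    return -0.5 * ((n - p) * math.log(sp2) + ld_v + ld_m + (n - p))


def reml_grid_argmax(y, X, S, resolution: float = 1e-4) -> float:
    """h2 maximising the profiled restricted likelihood over a uniform grid."""
    grid = np.arange(resolution, 1.0, resolution)
    vals = [reml_profile_loglik(y, X, S, h) for h in grid]
    return float(grid[int(np.argmax(vals))])


# ---------------------------------------------------------------------------
# small phenotype table helper
# ---------------------------------------------------------------------------


def phenotype_frame(ids, y, **extra) -> pd.DataFrame:
    df = pd.DataFrame({"animal": list(ids), "y": np.asarray(y, float)})
    for k, v in extra.items():
        df[k] = v
    return df
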