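"""Per-site evolvability indicators: F_IS and multilocus LD (I_A, r̄_d).

Three quantities summarise the balance of sexual vs clonal recruitment at
a sampling site:

* clonal richness R (from :mod:`clonescape.clonal`),
* the inbreeding coefficient F_IS = 1 - H_o/H_e, close to zero in large
  recombining populations and strongly negative where heterozygous
  clones are re-sampled,
* the (standardised) index of association I_A and r̄_d, multilocus
  linkage-disequilibrium summaries near zero under free recombination
  and elevated when clonality suppresses recombination.

All individuals of a site (sexually recruited and clonal copies alike)
enter these statistics: the clone signal is the point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonal import clonal_richness, detect_mlgs
from .genio import MISSING, SNPMatrix


@dataclass
class SiteStats:
    """Per-site summary row (see module docstring for the quantities)."""

    site: str
    n_individuals: int
    n_polymorphic_loci: int
    R: float
    G: int
    threshold: float
    fis: float
    Ho_sum: float
    He_sum: float
    ia: float
    r_bar_d: float
    p_value: float


def fis(m: SNPMatrix, unbiased: bool = False) -> tuple[float, pd.DataFrame]:
    """Multilocus and per-locus inbreeding coefficient for one site.

    Per locus, with allele frequency p from the non-missing calls:
    H_e = 2 p (1 - p), H_o = observed heterozygote fraction and
    f_l = 1 - H_o/H_e.  The multilocus value pools loci:
    F_IS = 1 - sum(H_o) / sum(H_e).  Monomorphic loci (within the site)
    are excluded.  ``unbiased`` applies the small-sample factor
    2n/(2n - 1) to H_e; the default leaves it out so a site consisting of
    one heterozygous clone yields exactly -1.
    """
    if m.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d = np.ma.masked_equal(m.dosages, MISSING)
    n_called = d.count(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d.sum(axis=0) / (2.0 * n_called)
    p = np.asarray(p, dtype=float)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        nn = np.asarray(n_called, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * (2 * nn) / np.maximum(2 * nn - 1, 1)
    ho = np.asarray((d == 1).sum(axis=0) / np.maximum(n_called, 1), dtype=float)
    poly = (he > 0) & (np.asarray(n_called) > 0)
    if not poly.any():
        raise ValueError("no within-site polymorphic loci; F_IS undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        f_l = np.where(poly, 1.0 - ho / np.where(he > 0, he, np.nan), np.nan)
    table = pd.DataFrame(
        {
            "locus": m.locus_ids,
            "p": p,
            "Ho": ho,
            "He": he,
            "f": f_l,
            "polymorphic": poly,
        }
    )
    multi = 1.0 - ho[poly].sum() / he[poly].sum()
    return float(multi), table


def _pair_locus_distances(X: np.ndarray) -> np.ndarray:
    """|g_a - g_b| for all pairs a<b, per locus; shape (n_pairs, L)."""
    n = X.shape[0]
    iu, ju = np.triu_indices(n, 1)
    return np.abs(X[iu] - X[ju])


def _rbar_d_from_pairs(P: np.ndarray) -> tuple[float, float]:
    """(I_A, r̄_d) from the pair x locus distance array.

    Population (divide-by-n_pairs) variances throughout; the r̄_d
    denominator 2 sum_{l<m} sqrt(V_l V_m) is computed as
    (sum sqrt V_l)^2 - sum V_l.
    """
    D = P.sum(axis=1)
    v_o = float(D.var())
    var_l = P.var(axis=0)
    v_e = float(var_l.sum())
    s1 = float(np.sqrt(var_l).sum())
    denom = s1 * s1 - v_e
    ia = v_o / v_e - 1.0 if v_e > 0 else np.nan
    rbd = (v_o - v_e) / denom if denom > 0 else np.nan
    return ia, rbd


def index_association(
    m: SNPMatrix, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float, float]:
    """Multilocus index of association for one site.

    Per pair (a, b) and locus l the distance is d_l = |g_a,l - g_b,l|.
    With D = sum_l d_l over loci, V_O the variance of D over pairs and
    V_E = sum_l Var(d_l):

        I_A  = V_O / V_E - 1
        r̄_d = (V_O - V_E) / (2 sum_{l<m} sqrt(Var(d_l) Var(d_m)))

    The permutation null shuffles each locus column independently across
    individuals (destroying inter-locus association, preserving locus-wise
    genotype frequencies); p = (1 + #{r̄_d_perm >= r̄_d_obs}) / (n_perm + 1).
    Missing cells are imputed with the locus mean dosage beforehand.
    """
    if m.n_individuals < 3:
        raise ValueError("need at least three individuals")
    X = m.dosages.astype(float)
    X[m.dosages == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    # keep within-site polymorphic loci only
    poly = X.std(axis=0) > 0
    X = X[:, poly]
    if X.shape[1] < 2:
        raise ValueError("need at least two within-site polymorphic loci")
    P = _pair_locus_distances(X)
    ia, rbd = _rbar_d_from_pairs(P)
    if n_perm <= 0:
        return ia, rbd, np.nan
    rng = np.random.default_rng(seed)
    n, L = X.shape
    hits = 0
    for _ in range(n_perm):
        Xp = np.empty_like(X)
        for l in range(L):
            Xp[:, l] = X[rng.permutation(n), l]
        _, r = _rbar_d_from_pairs(_pair_locus_distances(Xp))
        if r >= rbd:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ia, rbd, p


def site_stats(
    m: SNPMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """R, F_IS and r̄_d for every site of a (filtered) matrix.

    Clone contraction runs per site with a per-site predicted cutoff
    (falling back to exact-match contraction where the distance
    distribution carries no clone gap); F_IS and r̄_d use all individuals
    of the site.  Returns one row per site.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for site, child in zip(m.sites, ss.spawn(len(m.sites))):
        sub = m.restrict_to_site(site)
        a = detect_mlgs(sub, threshold=threshold)
        R = clonal_richness(a) if a.N >= 2 else np.nan
        try:
            f, table = fis(sub)
            npoly = int(table["polymorphic"].sum())
            ho, he = table.loc[table.polymorphic, ["Ho", "He"]].sum()
        except ValueError:
            f, npoly, ho, he = np.nan, 0, np.nan, np.nan
        try:
            site_seed = int(child.generate_state(1)[0] % (2**31))
            ia, rbd, p = index_association(sub, n_perm=n_perm, seed=site_seed)
        except ValueError:
            ia, rbd, p = np.nan, np.nan, np.nan
        rows.append(
            SiteStats(
                site=site,
                n_individuals=sub.n_individuals,
                n_polymorphic_loci=npoly,
                R=R,
                G=a.G,
                threshold=a.threshold,
                fis=f,
                Ho_sum=float(ho) if np.ndim(ho) == 0 else np.nan,
                He_sum=float(he) if np.ndim(he) == 0 else np.nan,
                ia=ia,
                r_bar_d=rbd,
                p_value=p,
            ).__dict__
        )
    return pd.DataFrame(rows)
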