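"""Morphometrics: undulation index, trait PCA and genotype/phenotype
dendrogram congruence.

Three thallus traits — frond width (FW), distance between dichotomies
(DBD) and the undulation index (UX, margin arc length over chord,
dimensionless >= 1) — summarise morphology; each individual carries the
mean of three branch measurements per trait.  Site-level dendrograms on
trait means are compared against a genetic-distance dendrogram with
cophenetic correlation and Robinson–Foulds distance to ask whether
field morphology recovers the genetic population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from .clonal import DistanceMatrix
from .syndata import MorphoTable


def undulation_index(margin: np.ndarray) -> float:
    """UX = polyline arc length / endpoint chord length.

    ``margin`` is an ordered (k, 2) array of points traced along the
    branch margin.  A straight margin gives 1; a semicircular margin
    over its diameter gives pi/2.  Invariant to rigid motions and
    uniform scaling.
    """
    pts = np.asarray(margin, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("margin must be an ordered sequence of >= 2 (x, y) points")
    seg = np.diff(pts, axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    chord = float(np.hypot(*(pts[-1] - pts[0])))
    if chord <= 1e-9 * max(arc, 1.0):
        raise ValueError("margin endpoints coincide; chord length is zero")
    return arc / chord


def individual_ux(branches: np.ndarray | list) -> float:
    """Individual UX: arithmetic mean of its (three) branch values."""
    vals = np.asarray(branches, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one branch UX value")
    return float(vals.mean())


def morpho_pca(t: MorphoTable, n_components: int = 3):
    """PCA of z-scored traits.  Returns (scores, variance_explained).

    Constant traits are dropped with a warning (they carry no
    information for the decomposition).
    """
    df = t.individuals
    if len(df) < 2:
        raise ValueError("need at least two individuals")
    traits = [c for c in MorphoTable.TRAITS if c in df.columns]
    X = df[traits].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
    if not keep.all():
        dropped = [t_ for t_, k in zip(traits, keep) if not k]
        warnings.warn(f"dropping constant traits: {dropped}")
        X = X[:, keep]
        traits = [t_ for t_, k in zip(traits, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("all traits constant")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    ncomp = min(n_components, S.size)
    var = S**2
    var_explained = (var / var.sum())[:ncomp]
    scores = U[:, :ncomp] * S[:ncomp]
    for c in range(ncomp):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            scores[:, c] *= -1.0
    out = pd.DataFrame(scores, columns=[f"PC{c + 1}" for c in range(ncomp)])
    for col in ("individual_id", "site", "lineage"):
        if col in df.columns:
            out.insert(0, col, df[col].to_numpy())
    return out, var_explained


# ----------------------------------------------- dendrogram congruence

@dataclass
class DendrogramComparison:
    """Morphology vs genetics site clustering, with congruence scores."""

    morpho_linkage: np.ndarray
    genetic_linkage: np.ndarray
    sites: list[str]
    cophenetic_correlation: float
    rf_distance: int
    max_rf: int

    def newick(self, which: str = "morpho") -> str:
        Z = self.morpho_linkage if which == "morpho" else self.genetic_linkage
        return _linkage_to_newick(Z, self.sites)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    reps = {i: (labels[i], 0.0) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        sa, ha = reps.pop(int(a))
        sb, hb = reps.pop(int(b))
        node = f"({sa}:{h / 2 - ha:.6g},{sb}:{h / 2 - hb:.6g})"
        reps[n + k] = (node, h / 2)
    root = next(iter(reps.values()))[0]
    return root + ";"


def _rf_distance(nwk1: str, nwk2: str) -> tuple[int, int]:
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    n_taxa = len(tns)
    return int(rf), 2 * (n_taxa - 3) if n_taxa > 3 else 2
    # max for unrooted binary trees


def site_dendrogram_compare(
    t: MorphoTable,
    genetic: DistanceMatrix,
    method: str = "average",
) -> DendrogramComparison:
    """Cluster sites by morphology and by genetics; score congruence.

    Morphology: Euclidean distance on z-scored site trait means,
    agglomerative clustering (``method``, default average linkage).
    Genetics: the supplied site-level distance matrix clustered the
    same way.  Sites present in only one input are dropped with a
    warning.  Congruence is the Pearson correlation of the two
    cophenetic distance matrices plus the Robinson–Foulds distance of
    the two dendrogram topologies.
    """
    df = t.individuals
    if "site" not in df.columns:
        raise ValueError("morphometric table needs a 'site' column")
    morpho_sites = sorted(df["site"].unique())
    gen_sites = list(genetic.ids)
    common = [s for s in morpho_sites if s in gen_sites]
    if len(common) < 3:
        raise ValueError("need at least three sites shared by both inputs")
    dropped = sorted(set(morpho_sites) ^ set(gen_sites))
    if dropped:
        warnings.warn(f"sites present in only one input dropped: {dropped}")
    traits = [c for c in MorphoTable.TRAITS if c in df.columns]
    means = df.groupby("site")[traits].mean().loc[common]
    Z = (means - means.mean()) / means.std(ddof=0).replace(0, 1.0)
    d_morpho = pdist(Z.to_numpy())
    idx = [gen_sites.index(s) for s in common]
    d_gen = squareform(genetic.values[np.ix_(idx, idx)], checks=False)
    Zm = linkage(d_morpho, method=method)
    Zg = linkage(d_gen, method=method)
    coph_m = squareform(cophenet(Zm))
    coph_g = squareform(cophenet(Zg))
    iu = np.triu_indices(len(common), 1)
    a, b = coph_m[iu], coph_g[iu]
    if a.std() == 0 or b.std() == 0:
        corr = 1.0 if np.allclose(a, b) else 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    rf, max_rf = _rf_distance(
        _linkage_to_newick(Zm, common), _linkage_to_newick(Zg, common)
    )
    return DendrogramComparison(Zm, Zg, common, corr, rf, max_rf)
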