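"""Clone (multilocus genotype) detection and clonal richness.

In partially clonal organisms the sampled "individuals" (ramets) may be
vegetative copies of fewer genetic individuals (genets).  This module
contracts ramets into genets from a pairwise genetic distance matrix:
distances concentrate near zero for copies of the same genet (differing
only by genotyping error), so a distance threshold placed in the gap
between the "same genet" peak and the rest of the distribution separates
clones from distinct genotypes.  Clonal richness R = (G-1)/(N-1)
summarises genotypic diversity (0 = monoclonal, 1 = all distinct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .genio import MISSING, SNPMatrix


class NoSharedLociError(ValueError):
    """A pair of individuals shares no non-missing locus."""


class CutoffError(ValueError):
    """The distance distribution does not support automatic cutoff choice."""


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise 'percentage of allelic differences'.

    ``values[a, b]`` is the mean per-allele difference between individuals
    over loci genotyped in both; ``counts[a, b]`` is that shared-locus
    count.  Entries are proportions in [0, 1] with a zero diagonal.
    """

    values: np.ndarray
    ids: list[str]
    counts: np.ndarray | None = None
    sites: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.nanmax(v, initial=0.0) > 1 + 1e-12 or np.nanmin(v, initial=0.0) < -1e-12:
            raise ValueError("distances must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index])


@dataclass
class MLGAssignment:
    """Partition of individuals into genets (contracted MLGs)."""

    genet_of: dict[str, str]
    threshold: float
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.genet_of)

    @property
    def G(self) -> int:
        return len(set(self.genet_of.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind, g in self.genet_of.items():
            out.setdefault(g, []).append(ind)
        return out

    def to_tsv(self, path, sites: dict[str, str] | None = None) -> None:
        rows = []
        for ind, g in self.genet_of.items():
            rows.append(
                {
                    "individual_id": ind,
                    "site": (sites or {}).get(ind, ""),
                    "genet": g,
                    "representative": int(self.representatives.get(g) == ind),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pairwise_distance(m: SNPMatrix, allow_missing_pairs: bool = False) -> DistanceMatrix:
    """Pairwise genetic distance as the proportion of allelic differences.

    For individuals a, b: d = sum_l |g_a,l - g_b,l| / (2 L_ab) over the
    L_ab loci called in both (dosage difference counts Aa<->AA as one and
    AA<->aa as two allelic differences).

    Raises :class:`NoSharedLociError` if some pair shares no locus, unless
    ``allow_missing_pairs`` (then NaN).
    """
    if m.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = m.dosages.astype(float)
    X[m.dosages == MISSING] = np.nan
    n = m.n_individuals
    vals = np.zeros((n, n))
    cnts = np.zeros((n, n), dtype=np.int64)
    obs = ~np.isnan(X)
    # row-chunked to bound the (n, n, L) broadcast
    chunk = max(1, int(2e7 // max(1, n * m.n_loci)))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        diff = np.abs(X[start:stop, None, :] - X[None, :, :])
        shared = obs[start:stop, None, :] & obs[None, :, :]
        cnt = shared.sum(axis=2)
        tot = np.nansum(np.where(shared, diff, 0.0), axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[start:stop] = np.where(cnt > 0, tot / (2.0 * cnt), np.nan)
        cnts[start:stop] = cnt
    iu = np.triu_indices(n, 1)
    if np.isnan(vals[iu]).any():
        if not allow_missing_pairs:
            raise NoSharedLociError(
                "some pair of individuals shares no non-missing locus"
            )
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, list(m.individual_ids), cnts, list(m.site_of_individual))


def merge_heights(d: DistanceMatrix) -> np.ndarray:
    """Sorted single-linkage merge heights of the distance matrix."""
    Z = linkage(d.condensed(), method="single")
    return np.sort(Z[:, 2])


def predict_cutoff_from_heights(heights, fraction: float = 0.5) -> float:
    """Clone-distance cutoff from sorted merge heights.

    The clone signal is a cluster of small merge heights separated by a
    gap from the remaining heights.  Among gaps between consecutive sorted
    heights whose lower endpoint is at most ``fraction`` of the largest
    height, the midpoint of the largest gap is returned (ties broken
    towards the lowest gap).
    """
    h = np.sort(np.asarray(heights, dtype=float))
    if h.size < 2:
        raise CutoffError(
            "fewer than 2 merge heights; choose a threshold manually"
        )
    limit = fraction * h[-1]
    lo = h[:-1]
    hi = h[1:]
    ok = lo <= limit
    if not ok.any():
        raise CutoffError("no candidate heights below fraction of max height")
    gaps = np.where(ok, hi - lo, -np.inf)
    if np.max(gaps) <= 0:
        raise CutoffError(
            "distance distribution has no gap; choose a threshold manually"
        )
    i = int(np.argmax(gaps))  # argmax returns the first (lowest) maximal gap
    return float((lo[i] + hi[i]) / 2.0)


def predict_cutoff(d: DistanceMatrix, fraction: float = 0.5) -> float:
    """Predict the clone cutoff from a distance matrix (see above)."""
    if np.unique(np.round(d.condensed(), 12)).size < 3:
        raise CutoffError(
            "need at least 3 distinct pairwise distances; choose a threshold manually"
        )
    return predict_cutoff_from_heights(merge_heights(d), fraction)


def contract_mlgs(
    d: DistanceMatrix, threshold: float, m: SNPMatrix | None = None
) -> MLGAssignment:
    """Contract individuals into genets at a distance threshold.

    Genets are connected components of the graph with an edge wherever
    d <= threshold (single-linkage contraction).  The representative of a
    genet is its lowest-missingness member when ``m`` is supplied, else
    the first member.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = (np.nan_to_num(d.values, nan=np.inf) <= threshold).astype(np.int8)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    # genet ids in order of first appearance
    seen: dict[int, str] = {}
    genet_of: dict[str, str] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = f"MLG{len(seen) + 1:04d}"
        genet_of[d.ids[i]] = seen[lab]
    reps: dict[str, str] = {}
    if m is not None:
        miss = dict(zip(m.individual_ids, m.individual_missingness()))
    else:
        miss = {i: 0.0 for i in d.ids}
    for g, members in MLGAssignment(genet_of, threshold).members().items():
        reps[g] = min(members, key=lambda ind: (miss.get(ind, 0.0), members.index(ind)))
    return MLGAssignment(genet_of, float(threshold), reps)


def clonal_richness(a: MLGAssignment) -> float:
    """Clonal richness R = (G - 1)/(N - 1)."""
    if a.N < 2:
        raise ValueError("clonal richness undefined for N < 2")
    return (a.G - 1) / (a.N - 1)


def detect_mlgs(
    m: SNPMatrix, fraction: float = 0.5, threshold: float | None = None
) -> MLGAssignment:
    """Distance -> predicted cutoff -> contraction in one step.

    If cutoff prediction is impossible (e.g. all genotypes identical, so
    there is no multi-peak distance distribution), falls back to
    threshold 0 — contraction of exactly identical genotypes.
    """
    d = pairwise_distance(m)
    if threshold is None:
        try:
            threshold = predict_cutoff(d, fraction)
        except CutoffError:
            threshold = 0.0
    return contract_mlgs(d, threshold, m)


def one_per_genet(m: SNPMatrix, a: MLGAssignment) -> SNPMatrix:
    """Drop ramets: keep only each genet's representative individual.

    Used before PCA / ancestry / demographic analyses so repeated
    genotypes do not distort frequencies.
    """
    keep = set(a.representatives.values())
    idx = [i for i, ind in enumerate(m.individual_ids) if ind in keep]
    return m.take_individuals(idx)
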