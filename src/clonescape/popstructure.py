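"""Individual-level genetic structure: PCA, ancestry proportions, NJ trees.

PCA and the ancestry analysis are meant to run on genet-level data (one
individual per multilocus genotype; see
:func:`clonescape.clonal.one_per_genet`) so repeated clonal genotypes do
not masquerade as population structure.  The neighbour-joining tree is
built on all individuals: near-zero terminal branches are the visual
signature of clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonal import DistanceMatrix, MLGAssignment, one_per_genet, pairwise_distance
from .genio import MISSING, SNPMatrix


# -------------------------------------------------------------------- PCA

def _imputed_centered(m: SNPMatrix, scale: bool) -> np.ndarray:
    X = m.dosages.astype(float)
    X[m.dosages == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    Xc = X - mean
    if scale:
        p = mean / 2.0
        denom = np.sqrt(p * (1 - p))
        denom[denom == 0] = 1.0
        Xc = Xc / denom
    return Xc


def pca(
    m: SNPMatrix,
    scale: bool = False,
    n_components: int = 10,
    mlg: MLGAssignment | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotype PCA.

    Missing cells are mean-imputed per locus, columns centred at the
    mean dosage and optionally scaled by sqrt(p(1-p)).  When an MLG
    assignment is given, ramets are dropped first (one individual per
    genet).  Each component is oriented so its largest-magnitude locus
    loading is positive.  Returns (scores, variance_explained).
    """
    if mlg is not None:
        m = one_per_genet(m, mlg)
    if m.n_individuals < 2 or m.n_loci < 2:
        raise ValueError("need at least 2 individuals and 2 loci")
    Xc = _imputed_centered(m, scale)
    if not Xc.any():
        raise ValueError("constant matrix has no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(n_components, S.size)
    var = S**2 / max(m.n_individuals - 1, 1)
    var_explained = (var / var.sum())[:ncomp]
    scores = U[:, :ncomp] * S[:ncomp]
    for c in range(ncomp):  # deterministic sign: top loading positive
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            scores[:, c] *= -1.0
    df = pd.DataFrame(
        scores, columns=[f"PC{c + 1}" for c in range(ncomp)]
    )
    df.insert(0, "site", m.site_of_individual)
    df.insert(0, "individual_id", m.individual_ids)
    return df, var_explained


# -------------------------------------------------------- ancestry (NMF)

def _project_rows_to_simplex(Y: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Y.shape
    U = np.sort(Y, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = U - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    rho = np.where(cond.any(axis=1), rho, 0)
    tau = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(Y - tau[:, None], 0.0)


def _one_hot(m: SNPMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(X, observed) with X shape (n, 3L): indicator of genotype 0/1/2."""
    n, L = m.dosages.shape
    X = np.zeros((n, 3 * L))
    obs = np.ones((n, 3 * L), dtype=bool)
    for g in range(3):
        X[:, g::3] = m.dosages == g
    miss = m.dosages == MISSING
    for g in range(3):
        obs[:, g::3] = ~miss
    return X, obs


@dataclass
class AncestryResult:
    """Fitted ancestry proportions Q and cluster genotype frequencies."""

    Q: np.ndarray
    F_geno: np.ndarray  # K x 3L per-locus genotype simplex
    K: int
    objective: float
    cross_entropy: float
    individual_ids: list[str]
    reps: int
    seed: int | None
    n_iter: int
    site_of_individual: list[str] = field(default_factory=list)

    @property
    def F(self) -> np.ndarray:
        """K x L cluster ALT-allele frequencies (from genotype probs)."""
        return 0.5 * self.F_geno[:, 1::3] + self.F_geno[:, 2::3]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.Q, axis=1)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.Q, columns=[f"K{k + 1}" for k in range(self.K)])
        df.insert(0, "individual_id", self.individual_ids)
        df.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        return (
            f"Ancestry (NMF) fit: K={self.K}, reps={self.reps}\n"
            f"  least-squares objective {self.objective:.4f}\n"
            f"  masked cross-entropy    {self.cross_entropy:.4f}\n"
            f"  individuals             {len(self.individual_ids)}"
        )


class AncestryNMF:
    """Least-squares ancestry decomposition of one-hot genotypes.

    Minimises ||X - Q F||^2 over Q (rows on the K-simplex) and F (a
    3-probability simplex per locus and cluster) by alternating
    projected-gradient steps with monotone backtracking, so the
    objective never increases.  Model choice across K uses the
    cross-entropy of held-out (masked) cells.
    """

    def __init__(
        self,
        m: SNPMatrix,
        K: int,
        holdout_fraction: float = 0.05,
        tol: float = 1e-6,
        max_iter: int = 500,
    ) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > m.n_individuals:
            raise ValueError("K cannot exceed the number of individuals")
        self.m = m
        self.K = K
        self.holdout_fraction = holdout_fraction
        self.tol = tol
        self.max_iter = max_iter

    # one projected-gradient step with backtracking on either factor
    @staticmethod
    def _pg_step(X, W, Q, F, update_q: bool) -> tuple[np.ndarray, float]:
        R = W * (Q @ F - X)
        obj = float((R**2).sum())
        if update_q:
            G = 2.0 * R @ F.T
            lip = 2.0 * np.linalg.norm(F @ F.T, 2) + 1e-12
            step = 1.0 / lip
            for _ in range(20):
                Qn = _project_rows_to_simplex(Q - step * G)
                Rn = W * (Qn @ F - X)
                if float((Rn**2).sum()) <= obj:
                    return Qn, float((Rn**2).sum())
                step *= 0.5
            return Q, obj
        G = 2.0 * Q.T @ R
        lip = 2.0 * np.linalg.norm(Q.T @ Q, 2) + 1e-12
        step = 1.0 / lip
        K = Q.shape[1]
        L3 = F.shape[1]
        for _ in range(20):
            Fn = F - step * G
            # per-locus 3-simplex projection, vectorised over (K, L)
            Fn = (
                _project_rows_to_simplex(Fn.reshape(K, L3 // 3, 3).reshape(-1, 3))
                .reshape(K, L3 // 3, 3)
                .reshape(K, L3)
            )
            Rn = W * (Q @ Fn - X)
            if float((Rn**2).sum()) <= obj:
                return Fn, float((Rn**2).sum())
            step *= 0.5
        return F, obj

    def fit(self, reps: int = 5, seed: int | None = None) -> AncestryResult:
        X, obs = _one_hot(self.m)
        n, L3 = X.shape
        rng = np.random.default_rng(seed)
        # mask a holdout of loci cells (whole genotype triplets)
        L = L3 // 3
        hold = rng.random((n, L)) < self.holdout_fraction
        W = obs.copy()
        for g in range(3):
            W[:, g::3] &= ~hold
        W = W.astype(float)
        best = None
        for rep in range(reps):
            Q = rng.dirichlet(np.ones(self.K), size=n)
            F = rng.dirichlet(np.ones(3), size=(self.K, L)).reshape(self.K, L3)
            prev = np.inf
            it = 0
            for it in range(1, self.max_iter + 1):
                Q, _ = self._pg_step(X, W, Q, F, update_q=True)
                F, obj = self._pg_step(X, W, Q, F, update_q=False)
                if prev - obj < self.tol * max(prev, 1.0):
                    prev = obj
                    break
                prev = obj
            if best is None or prev < best[0]:
                best = (prev, Q, F, it)
        obj, Q, F, n_iter = best
        # masked cross-entropy on the held-out cells
        pred = Q @ F
        eps = 1e-9
        mask_cells = hold & (self.m.dosages != MISSING)
        if mask_cells.any():
            ii, jj = np.where(mask_cells)
            gg = self.m.dosages[ii, jj]
            probs = np.clip(pred[ii, 3 * jj + gg], eps, 1.0)
            ce = float(-np.mean(np.log(probs)))
        else:
            ce = np.nan
        return AncestryResult(
            Q=Q,
            F_geno=F,
            K=self.K,
            objective=obj,
            cross_entropy=ce,
            individual_ids=list(self.m.individual_ids),
            reps=reps,
            seed=seed,
            n_iter=n_iter,
            site_of_individual=list(self.m.site_of_individual),
        )


def ancestry_nmf(
    m: SNPMatrix, K: int, reps: int = 5, seed: int | None = None, **kwargs
) -> AncestryResult:
    """Fit ancestry proportions for one K (see :class:`AncestryNMF`)."""
    return AncestryNMF(m, K, **kwargs).fit(reps=reps, seed=seed)


def choose_k(
    m: SNPMatrix, k_values, reps: int = 3, seed: int | None = None
) -> pd.DataFrame:
    """Masked cross-entropy across candidate K (lower is better)."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for K, child in zip(k_values, ss.spawn(len(list(k_values)))):
        res = ancestry_nmf(m, K, reps=reps, seed=int(child.generate_state(1)[0] % 2**31))
        rows.append({"K": K, "cross_entropy": res.cross_entropy, "objective": res.objective})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- NJ trees

@dataclass
class TreeWithSupport:
    """Unrooted NJ tree with bootstrap split support.

    ``tree`` is a scikit-bio TreeNode; internal node names hold the
    bootstrap proportion (as a percentage) when bootstrapping was run.
    ``n_clamped`` counts negative NJ branch lengths clamped to zero.
    """

    tree: object
    support: dict[frozenset, float]
    boot: int
    n_clamped: int = 0

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def _splits(tree, leaves: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each keyed by the side not containing
    an arbitrary fixed reference leaf."""
    ref = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def nj_tree(
    d: DistanceMatrix,
    boot: int = 0,
    m: SNPMatrix | None = None,
    seed: int | None = None,
) -> TreeWithSupport:
    """Neighbour-joining tree with optional locus-bootstrap support.

    Support for each internal split is the proportion of bootstrap
    replicate trees (loci resampled with replacement, distances and NJ
    recomputed) containing that split; it is written into the internal
    node names as a percentage.  Bootstrapping requires the genotype
    matrix ``m``.  Negative NJ branch lengths are clamped to zero and
    counted in ``n_clamped``.
    """
    import skbio

    if d.n < 3:
        raise ValueError("need at least three individuals")
    dm = skbio.DistanceMatrix(d.values, ids=d.ids)
    tree = skbio.tree.nj(dm)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    leaves = frozenset(d.ids)
    support: dict[frozenset, float] = {}
    if boot > 0:
        if m is None:
            raise ValueError("bootstrap requires the genotype matrix m")
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {s: 0 for s in _splits(tree, leaves)}
        for _ in range(boot):
            idx = rng.integers(0, m.n_loci, size=m.n_loci)
            db = pairwise_distance(m.take_loci(idx), allow_missing_pairs=True)
            vals = np.nan_to_num(db.values, nan=1.0)
            rep = skbio.tree.nj(skbio.DistanceMatrix(vals, ids=db.ids))
            rep_splits = _splits(rep, leaves)
            for s in counts:
                if s in rep_splits:
                    counts[s] += 1
        support = {s: c / boot for s, c in counts.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            key = side if min(leaves) not in side else leaves - side
            if key in support:
                node.name = f"{100 * support[key]:.0f}"
    return TreeWithSupport(tree, support, boot, n_clamped)
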