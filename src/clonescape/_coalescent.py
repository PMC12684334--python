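"""Two-deme structured-coalescent engine (numba-jitted).

Simulates genealogies of ``n1h + n2h`` haploid lineages sampled from two
demes under a piecewise-constant history: per-epoch deme sizes and
backward migration rates up to the split time, then a single ancestral
deme.  Time is measured in units of 2*N_ref generations; a deme of
relative size nu coalesces each lineage pair at rate 1/nu and a lineage
in deme i hops to deme j at rate M_ij per unit time.

Two entry points:

* :func:`branch_sfs` accumulates, over replicate genealogies, the total
  branch length subtending (i, j) sampled copies in (deme1, deme2) — the
  expected joint SFS is theta/2 times the mean of this array.
* :func:`mutation_sites` additionally drops infinite-sites mutations at
  rate theta/2 per lineage per unit time and records the descendant sets
  of each resulting segregating site as two int64 bitmasks (hence at
  most 62 haploid samples per deme).

Epoch arrays describe [0, t_split): ``ep_end`` holds increasing epoch end
times whose last entry is the split time; after it all lineages merge
into one deme of size ``na``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_engine(seed):
    np.random.seed(seed)


@njit(cache=True)
def _pick_slot(pop, k, target, a):
    """Return the slot index of the a-th active lineage in deme ``target``."""
    cnt = 0
    for i in range(k):
        if pop[i] == target:
            if cnt == a:
                return i
            cnt += 1
    return -1


@njit(cache=True)
def branch_sfs(n1h, n2h, ep_end, ep_nu1, ep_nu2, ep_m12, ep_m21, na, n_reps, out):
    """Accumulate branch lengths by descendant configuration into ``out``.

    ``out`` has shape (n1h + 1, n2h + 1) and is added to in place; divide
    by ``n_reps`` for the per-genealogy expectation.
    """
    k0 = n1h + n2h
    c1 = np.empty(k0, np.int64)
    c2 = np.empty(k0, np.int64)
    pop = np.empty(k0, np.int64)
    n_ep = ep_end.shape[0]
    for _rep in range(n_reps):
        for i in range(n1h):
            c1[i] = 1
            c2[i] = 0
            pop[i] = 0
        for i in range(n1h, k0):
            c1[i] = 0
            c2[i] = 1
            pop[i] = 1
        k = k0
        t = 0.0
        ep = 0
        guard = 0
        while k > 1:
            guard += 1
            if guard > 100_000_000:
                raise RuntimeError("coalescent did not converge")
            if ep < n_ep:
                te = ep_end[ep]
                nu1 = ep_nu1[ep]
                nu2 = ep_nu2[ep]
                m12 = ep_m12[ep]
                m21 = ep_m21[ep]
            else:
                te = 1.0e300
                nu1 = na
                nu2 = 1.0
                m12 = 0.0
                m21 = 0.0
                for i in range(k):
                    pop[i] = 0
            while k > 1 and t < te:
                k1 = 0
                for i in range(k):
                    if pop[i] == 0:
                        k1 += 1
                k2 = k - k1
                rc1 = k1 * (k1 - 1) * 0.5 / nu1
                rc2 = k2 * (k2 - 1) * 0.5 / nu2
                rm1 = k1 * m12
                rm2 = k2 * m21
                rate = rc1 + rc2 + rm1 + rm2
                if rate <= 0.0:
                    dt = te - t
                    for i in range(k):
                        out[c1[i], c2[i]] += dt
                    t = te
                    break
                dt = -np.log(np.random.random()) / rate
                if t + dt >= te:
                    dt = te - t
                    for i in range(k):
                        out[c1[i], c2[i]] += dt
                    t = te
                    break
                for i in range(k):
                    out[c1[i], c2[i]] += dt
                t += dt
                u = np.random.random() * rate
                if u < rc1 + rc2:
                    target = 0 if u < rc1 else 1
                    kk = k1 if target == 0 else k2
                    a = int(np.random.random() * kk)
                    b = int(np.random.random() * (kk - 1))
                    if b >= a:
                        b += 1
                    ia = _pick_slot(pop, k, target, a)
                    ib = _pick_slot(pop, k, target, b)
                    c1[ia] += c1[ib]
                    c2[ia] += c2[ib]
                    c1[ib] = c1[k - 1]
                    c2[ib] = c2[k - 1]
                    pop[ib] = pop[k - 1]
                    k -= 1
                elif u < rc1 + rc2 + rm1:
                    a = int(np.random.random() * k1)
                    i = _pick_slot(pop, k, 0, a)
                    pop[i] = 1
                else:
                    a = int(np.random.random() * k2)
                    i = _pick_slot(pop, k, 1, a)
                    pop[i] = 0
            if t >= te and ep < n_ep:
                ep += 1
    return out


@njit(cache=True)
def mutation_sites(
    n1h,
    n2h,
    ep_end,
    ep_nu1,
    ep_nu2,
    ep_m12,
    ep_m21,
    na,
    theta_half,
    n_loci,
    mask1_out,
    mask2_out,
    locus_out,
):
    """Simulate ``n_loci`` unlinked loci; drop infinite-sites mutations.

    Each mutation yields one segregating site recorded as the carrier
    bitmasks of the two demes plus its locus index.  Returns the number
    of sites written; raises if the output arrays are exhausted.
    """
    k0 = n1h + n2h
    c1 = np.empty(k0, np.int64)
    c2 = np.empty(k0, np.int64)
    b1 = np.empty(k0, np.int64)
    b2 = np.empty(k0, np.int64)
    pop = np.empty(k0, np.int64)
    n_ep = ep_end.shape[0]
    cap = mask1_out.shape[0]
    ns = 0
    for locus in range(n_loci):
        for i in range(n1h):
            c1[i] = 1
            c2[i] = 0
            b1[i] = 1 << i
            b2[i] = 0
            pop[i] = 0
        for i in range(n1h, k0):
            c1[i] = 0
            c2[i] = 1
            b1[i] = 0
            b2[i] = 1 << (i - n1h)
            pop[i] = 1
        k = k0
        t = 0.0
        ep = 0
        guard = 0
        while k > 1:
            guard += 1
            if guard > 100_000_000:
                raise RuntimeError("coalescent did not converge")
            if ep < n_ep:
                te = ep_end[ep]
                nu1 = ep_nu1[ep]
                nu2 = ep_nu2[ep]
                m12 = ep_m12[ep]
                m21 = ep_m21[ep]
            else:
                te = 1.0e300
                nu1 = na
                nu2 = 1.0
                m12 = 0.0
                m21 = 0.0
                for i in range(k):
                    pop[i] = 0
            while k > 1 and t < te:
                k1 = 0
                for i in range(k):
                    if pop[i] == 0:
                        k1 += 1
                k2 = k - k1
                rc1 = k1 * (k1 - 1) * 0.5 / nu1
                rc2 = k2 * (k2 - 1) * 0.5 / nu2
                rm1 = k1 * m12
                rm2 = k2 * m21
                rate = rc1 + rc2 + rm1 + rm2
                if rate <= 0.0:
                    dt = te - t
                else:
                    dt = -np.log(np.random.random()) / rate
                    if t + dt >= te:
                        dt = te - t
                        rate = 0.0  # event falls beyond the epoch
                nm = np.random.poisson(theta_half * dt * k)
                for _ in range(nm):
                    i = int(np.random.random() * k)
                    if ns >= cap:
                        raise RuntimeError("site buffer exhausted; enlarge capacity")
                    mask1_out[ns] = b1[i]
                    mask2_out[ns] = b2[i]
                    locus_out[ns] = locus
                    ns += 1
                t += dt
                if rate <= 0.0:
                    t = te
                    break
                u = np.random.random() * rate
                if u < rc1 + rc2:
                    target = 0 if u < rc1 else 1
                    kk = k1 if target == 0 else k2
                    a = int(np.random.random() * kk)
                    b = int(np.random.random() * (kk - 1))
                    if b >= a:
                        b += 1
                    ia = _pick_slot(pop, k, target, a)
                    ib = _pick_slot(pop, k, target, b)
                    c1[ia] += c1[ib]
                    c2[ia] += c2[ib]
                    b1[ia] |= b1[ib]
                    b2[ia] |= b2[ib]
                    c1[ib] = c1[k - 1]
                    c2[ib] = c2[k - 1]
                    b1[ib] = b1[k - 1]
                    b2[ib] = b2[k - 1]
                    pop[ib] = pop[k - 1]
                    k -= 1
                elif u < rc1 + rc2 + rm1:
                    a = int(np.random.random() * k1)
                    i = _pick_slot(pop, k, 0, a)
                    pop[i] = 1
                else:
                    a = int(np.random.random() * k2)
                    i = _pick_slot(pop, k, 1, a)
                    pop[i] = 0
            if t >= te and ep < n_ep:
                ep += 1
    return ns
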