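"""First-principles reference implementations used as test oracles.

Each of these is intentionally independent of the package's own code paths:
explicit normal equations, a literal step-up scan, breadth-first search, and
exhaustive enumeration of group labelings.
"""

import itertools

import numpy as np
import pandas as pd


def ols_normal_equations(X, y):
    """Textbook OLS via the normal equations."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), dof


def bh_stepup_bruteforce(p, alpha):
    """Largest k with p_(k) <= k*alpha/m; reject the k smallest p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def components_bfs(flags, adjacency):
    """Connected components of the flagged subgraph by breadth-first search."""
    adj = adjacency.tolil().rows
    seen = set()
    comps = []
    for start in np.flatnonzero(flags):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            for v in adj[u]:
                if flags[v] and v not in comp:
                    queue.append(v)
        seen |= comp
        comps.append(frozenset(int(i) for i in comp))
    return set(comps)


def mwu_exact_enumeration(a, b):
    """Two-sided exact p for the rank-sum U over all C(n_a+n_b, n_a) labelings."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    mu = n_a * len(b) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    extreme = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us)
    return u_obs, extreme / len(us)
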