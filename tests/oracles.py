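"""Independent oracles used by the tests.

These deliberately take different computational routes from the package:
the tabular (recursive dense) relationship matrix, gene-dropping Monte
Carlo for base-group contributions, and direct dense evaluation of the
group-augmented factorisations.
"""

import numpy as np


def tabular_A(sire, dam):
    """Dense numerator relationship matrix by the tabular method."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def tabular_A_gamma(sire, dam, gamma):
    """Tabular A over a metafounder-augmented pedigree.

    ``sire``/``dam`` are codes into the augmented ordering where the first
    g rows are the metafounders (no parents); their block is ``gamma``.
    """
    g = gamma.shape[0]
    n = len(sire)
    A = np.zeros((g + n, g + n))
    A[:g, :g] = gamma
    for i in range(n):
        k = g + i
        s, d = sire[i], dam[i]
        row = 0.5 * (A[s, :k] + A[d, :k])
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + 0.5 * A[s, d]
    return A


def dense_astar(sire, dam, sire_group, dam_group, n_groups, dvec):
    """A* by direct evaluation of M' D^{-1} M with the group-augmented
    gene-flow matrix M (n x (n+g): 1 on the animal, -1/2 on each parent or
    group slot)."""
    n = len(sire)
    M = np.zeros((n, n + n_groups))
    for i in range(n):
        M[i, i] = 1.0
        for p, grp in ((sire[i], sire_group[i]), (dam[i], dam_group[i])):
            col = p if p >= 0 else n + grp
            M[i, col] -= 0.5
    return M.T @ np.diag(1.0 / dvec) @ M


def gene_drop_Q(sire, dam, sire_group, dam_group, n_groups, n_drops, rng):
    """Monte-Carlo base-group contributions: drop one gene per animal and
    record which group the lineage terminates in."""
    n = len(sire)
    counts = np.zeros((n, n_groups))
    for _ in range(n_drops):
        origin = np.zeros(n, dtype=np.int64)
        for i in range(n):
            if rng.random() < 0.5:
                p, grp = sire[i], sire_group[i]
            else:
                p, grp = dam[i], dam_group[i]
            origin[i] = origin[p] if p >= 0 else grp
        for i in range(n):
            counts[i, origin[i]] += 1
    return counts / n_drops


def random_pedigree(n, rng, p_missing=0.15, n_lines=2):
    """Random topologically-ordered pedigree (codes; -1 = missing parent)."""
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    lines = np.array([f"L{rng.integers(n_lines) + 1}" for _ in range(n)],
                     dtype=object)
    for i in range(2, n):
        if rng.random() > p_missing:
            sire[i] = rng.integers(0, i)
        if rng.random() > p_missing:
            d = rng.integers(0, i)
            dam[i] = d if d != sire[i] else -1
    return sire, dam, lines
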