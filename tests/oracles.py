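"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by the most transparent method
available (quadratic-space DP, exhaustive subset enumeration, naive path
walks) and share no code with the implementation they check.
"""

from __future__ import annotations

from itertools import combinations

NEG = float("-inf")

MATCH = 1.0
MISMATCH = -2.0
OPEN = -7.0  # first gap column: open (-5) + extend (-2)
EXTEND = -2.0


def _sub(a: str, b: str) -> float:
    return MATCH if a == b and a in "ACGT" else MISMATCH


def semiglobal_align_oracle(a: str, b: str) -> dict:
    """Exhaustive affine-gap DP with free terminal gaps, with traceback.

    Returns score, matches, aligned columns (terminal overhangs excluded)
    and the covered span of the shorter sequence. Quadratic space, plain
    Python — intended for sequences of length <= ~100.
    """
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap columns consuming a
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap columns consuming b

    def start(i: int, j: int) -> float:
        # free leading gaps: the path may begin on the top or left boundary
        return 0.0 if i == 0 or j == 0 else NEG

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = max(
                M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], start(i - 1, j - 1)
            )
            M[i][j] = _sub(a[i - 1], b[j - 1]) + best_prev
            X[i][j] = max(
                M[i - 1][j] + OPEN,
                X[i - 1][j] + EXTEND,
                Y[i - 1][j] + OPEN,
                start(i - 1, j) + OPEN,
            )
            Y[i][j] = max(
                M[i][j - 1] + OPEN,
                Y[i][j - 1] + EXTEND,
                X[i][j - 1] + OPEN,
                start(i, j - 1) + OPEN,
            )
    # free trailing gaps: the path may end on the bottom or right boundary
    # in any state (a charged gap run may precede the free remainder)
    score, end = 0.0, None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if i == m or j == n:
                for st, mat in (("M", M), ("X", X), ("Y", Y)):
                    if mat[i][j] > score:
                        score, end = mat[i][j], (st, i, j)
    if end is None:
        return {
            "score": 0.0,
            "matches": 0,
            "columns": 0,
            "identity": 0.0,
            "aligned_fraction": 0.0,
        }

    # walk the optimal path back to a boundary start, recording each column
    state, i, j = end
    path: list[tuple[str, int, int]] = []
    while True:
        path.append((state, i, j))
        if state == "M":
            target = M[i][j] - _sub(a[i - 1], b[j - 1])
            opts = (
                ("M", M[i - 1][j - 1]),
                ("X", X[i - 1][j - 1]),
                ("Y", Y[i - 1][j - 1]),
            )
            i, j = i - 1, j - 1
            if start(i, j) >= target - 1e-9:
                break
        elif state == "X":
            target = X[i][j]
            opts = (
                ("M", M[i - 1][j] + OPEN),
                ("X", X[i - 1][j] + EXTEND),
                ("Y", Y[i - 1][j] + OPEN),
            )
            i = i - 1
            if start(i, j) + OPEN >= target - 1e-9:
                break
        else:
            target = Y[i][j]
            opts = (
                ("M", M[i][j - 1] + OPEN),
                ("Y", Y[i][j - 1] + EXTEND),
                ("X", X[i][j - 1] + OPEN),
            )
            j = j - 1
            if start(i, j) + OPEN >= target - 1e-9:
                break
        state = next(st for st, val in opts if abs(val - target) < 1e-9)
    path.reverse()

    # the core runs between the first and the last aligned pair
    m_positions = [k for k, (st, _, _) in enumerate(path) if st == "M"]
    matches = columns = 0
    covered_a = covered_b = 0
    if m_positions:
        core = path[m_positions[0] : m_positions[-1] + 1]
        for st, ci, cj in core:
            columns += 1
            if st == "M" and _sub(a[ci - 1], b[cj - 1]) == MATCH:
                matches += 1
        _, i0, j0 = core[0]
        _, i1, j1 = core[-1]
        covered_a = i1 - i0 + 1
        covered_b = j1 - j0 + 1
    shorter = min(m, n)
    covered = covered_a if m <= n else covered_b
    return {
        "score": score,
        "matches": matches,
        "columns": columns,
        "identity": 100.0 * matches / columns if columns else 0.0,
        "aligned_fraction": covered / shorter,
    }


def subset_mean_richness(matrix, t: int) -> float:
    """Mean observed richness over all C(T, t) subsets of sampling units."""
    n_units = matrix.shape[1]
    vals = []
    for cols in combinations(range(n_units), t):
        sub = matrix[:, list(cols)]
        vals.append(int((sub.sum(axis=1) > 0).sum()))
    return sum(vals) / len(vals)


def pairwise_path_distance(tree, label_a: str, label_b: str) -> float:
    """Patristic distance by naive root-path walking (no library calls)."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out
    pa = path_to_root(leaves[label_a])
    pb = path_to_root(leaves[label_b])
    sa = set(id(x) for x in pb)
    dist = 0.0
    for node in pa:
        if id(node) in sa:
            mrca = node
            break
        dist += node.edge.length or 0.0
    for node in pb:
        if node is mrca:
            break
        dist += node.edge.length or 0.0
    return dist
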