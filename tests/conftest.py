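import numpy as np
import pytest
import scipy.sparse as sp

from cotransmit.expression_io import ExpressionMatrix

# Printed inclusive ("at least") counts for the Ciona intestinalis larval
# brain: 644 neurons; GABA 495, acetylcholine 152, glutamate 19; pairwise
# co-expression 134 (GABA+ACh), 18 (GABA+Glut), 2 (ACh+Glut); triple 2.
CIONA_CLASSES = ["GABAergic", "Cholinergic", "Glutamatergic"]
CIONA_TOTAL = 644
CIONA_INCLUSIVE = {
    frozenset({"GABAergic"}): 495,
    frozenset({"Cholinergic"}): 152,
    frozenset({"Glutamatergic"}): 19,
    frozenset({"GABAergic", "Cholinergic"}): 134,
    frozenset({"GABAergic", "Glutamatergic"}): 18,
    frozenset({"Cholinergic", "Glutamatergic"}): 2,
    frozenset({"GABAergic", "Cholinergic", "Glutamatergic"}): 2,
}
# Hand-derived Möbius inversion of the above (checked by brute-force
# construction of a 644-cell multiset realizing the inclusive counts).
CIONA_EXCLUSIVE = {
    frozenset(): 130,
    frozenset({"GABAergic"}): 345,
    frozenset({"Cholinergic"}): 18,
    frozenset({"Glutamatergic"}): 1,
    frozenset({"GABAergic", "Cholinergic"}): 132,
    frozenset({"GABAergic", "Glutamatergic"}): 16,
    frozenset({"Cholinergic", "Glutamatergic"}): 0,
    frozenset({"GABAergic", "Cholinergic", "Glutamatergic"}): 2,
}


def make_matrix(counts, cell_ids=None, gene_ids=None, normalized=None) -> ExpressionMatrix:
    counts = np.asarray(counts)
    n, g = counts.shape
    return ExpressionMatrix(
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        counts=sp.csr_matrix(counts),
        normalized=None if normalized is None else sp.csr_matrix(np.asarray(normalized)),
    )


@pytest.fixture
def ciona_inclusive():
    return dict(CIONA_INCLUSIVE)


def brute_force_counts(cell_subsets, class_names):
    """Independent oracle: test every subset of the class universe against every cell."""
    from itertools import combinations

    exclusive, inclusive = {}, {}
    all_subsets = [
        frozenset(c)
        for r in range(len(class_names) + 1)
        for c in combinations(class_names, r)
    ]
    for s in all_subsets:
        exclusive[s] = sum(1 for cs in cell_subsets if cs == s)
        inclusive[s] = sum(1 for cs in cell_subsets if s <= cs)
    return exclusive, inclusive
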