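import numpy as np
import pytest
import scipy.linalg

import branchsim as bs
from branchsim.hines import apply_boundary


def make_arrays(p, a, b, d, rhs, v=None, has_parent=False):
    p = np.asarray(p, dtype=np.int64)
    return bs.SolverArrays(p, np.asarray(a, float), np.asarray(b, float),
                           np.asarray(d, float), np.asarray(rhs, float),
                           np.zeros(p.size) if v is None else np.asarray(v, float),
                           has_parent=has_parent)


class TestTriangulation:
    def test_two_compartment_chain_elimination(self):
        arr = make_arrays([-1, 0], [0, -1], [0, -1], [4, 4], [8, 8])
        out = bs.backward_triangulate(arr)
        assert out is None
        assert arr.d[0] == pytest.approx(3.75)   # 4 - (-1/4)·(-1)
        assert arr.rhs[0] == pytest.approx(10.0)  # 8 - (-1/4)·8

    def test_y_tree_elimination(self):
        arr = make_arrays([-1, 0, 0], [0, -1, -1], [0, -1, -1],
                          [3, 2, 2], [1, 0, 0])
        bs.backward_triangulate(arr)
        assert arr.d[0] == pytest.approx(2.0)    # each child folds -0.5
        assert arr.rhs[0] == pytest.approx(1.0)

    def test_boundary_contribution_of_leaf_subtree(self):
        arr = make_arrays([-1], [-1.0], [-1.0], [2.0], [4.0], has_parent=True)
        bc = bs.backward_triangulate(arr)
        assert bc.delta_d == pytest.approx(-0.5)   # -(a0/d0)·b0
        assert bc.delta_rhs == pytest.approx(2.0)  # -(a0/d0)·rhs0

    def test_zero_pivot_raises(self):
        arr = make_arrays([-1, 0], [0, -1], [0, -1], [4, 0], [1, 1])
        with pytest.raises(bs.SingularMatrixError):
            bs.backward_triangulate(arr)

    def test_a_and_b_untouched_by_solve(self):
        rng = np.random.default_rng(5)
        arr = bs.random_solver_tree(40, rng)
        a0, b0 = arr.a.copy(), arr.b.copy()
        bs.solve_tree(arr)
        np.testing.assert_array_equal(arr.a, a0)
        np.testing.assert_array_equal(arr.b, b0)


class TestSubstitution:
    def test_two_compartment_chain_solution(self):
        arr = make_arrays([-1, 0], [0, -1], [0, -1], [4, 4], [8, 8])
        dv = bs.solve_tree(arr)
        # dense solve of [[4,-1],[-1,4]] x = [8,8] → (8/3, 8/3)
        np.testing.assert_allclose(dv, [8 / 3, 8 / 3], rtol=1e-14)

    def test_y_tree_solution(self):
        arr = make_arrays([-1, 0, 0], [0, -1, -1], [0, -1, -1],
                          [3, 2, 2], [1, 0, 0])
        dv = bs.solve_tree(arr)
        np.testing.assert_allclose(dv, [0.5, 0.25, 0.25], rtol=1e-14)

    def test_single_compartment(self):
        arr = make_arrays([-1], [0.0], [0.0], [2.0], [4.0])
        assert bs.solve_tree(arr)[0] == pytest.approx(2.0)

    def test_identity_like_system(self):
        rhs = np.array([1.0, -2.0, 3.5])
        arr = make_arrays([-1, 0, 1], [0, 0, 0], [0, 0, 0],
                          [1, 1, 1], rhs.copy())
        np.testing.assert_array_equal(bs.solve_tree(arr), rhs)

    def test_missing_parent_delta_raises(self):
        arr = make_arrays([-1], [-1.0], [-1.0], [2.0], [4.0], has_parent=True)
        bs.backward_triangulate(arr)
        with pytest.raises(bs.SynchronizationError):
            bs.forward_substitute(arr)


@pytest.mark.parametrize("n", [3, 17, 50, 200])
def test_solver_matches_dense_oracle(n):
    """Tree solve equals a dense LU solve of the assembled sparse matrix."""
    rng = np.random.default_rng(n)
    for _ in range(20):
        arr = bs.random_solver_tree(n, rng)
        dense = bs.assemble_dense(arr)
        expect = scipy.linalg.solve(dense, arr.rhs.copy())
        got = bs.solve_tree(arr)
        scale = np.abs(expect).max()
        assert np.abs(got - expect).max() / scale < 1e-10


def test_split_solve_composes_to_monolithic():
    """Eliminating a child subtree and folding its boundary contribution
    into the parent's leaf row reproduces the whole-tree solve."""
    rng = np.random.default_rng(77)
    for _ in range(25):
        n = int(rng.integers(6, 40))
        whole = bs.random_solver_tree(n, rng)
        ref = bs.solve_tree(
            bs.SolverArrays(whole.p.copy(), whole.a.copy(), whole.b.copy(),
                            whole.d.copy(), whole.rhs.copy(), whole.v.copy()))
        # split: rows [cut..n) are DFS-contiguous iff their parents stay
        # inside; find a cut whose tail is a valid subtree
        cut = None
        for c in range(n - 1, 1, -1):
            tail = np.arange(c, n)
            if np.all(np.isin(whole.p[tail[1:]], tail)) and whole.p[c] < c:
                cut = c
                break
        if cut is None:
            continue
        q = int(whole.p[cut])
        child = bs.SolverArrays(
            np.concatenate([[-1], whole.p[cut + 1:] - cut]),
            whole.a[cut:].copy(), whole.b[cut:].copy(),
            whole.d[cut:].copy(), whole.rhs[cut:].copy(),
            whole.v[cut:].copy(), has_parent=True)
        parent = bs.SolverArrays(
            whole.p[:cut].copy(), whole.a[:cut].copy(), whole.b[:cut].copy(),
            whole.d[:cut].copy(), whole.rhs[:cut].copy(), whole.v[:cut].copy())
        bc = bs.backward_triangulate(child)
        apply_boundary(parent, q, bc)
        bs.backward_triangulate(parent)
        bs.forward_substitute(parent)
        bs.forward_substitute(child, parent_delta_v=parent.rhs[q])
        got = np.concatenate([parent.rhs, child.rhs])
        assert np.abs(got - ref).max() < 1e-12 * max(1.0, np.abs(ref).max())


def test_setup_matrix_single_passive_compartment():
    """d = C/dt + G; rhs = 0 at the leak reversal potential (equilibrium)."""
    arr = make_arrays([-1], [0.0], [0.0], [0.0], [0.0], v=[-65.0])
    G = np.array([0.1])
    i_total = np.array([0.1 * (-65.0 - -65.0)])
    bs.setup_matrix(arr, G, i_total, C=np.array([1.0]), dt=0.025)
    assert arr.d[0] == pytest.approx(1.0 / 0.025 + 0.1)  # 40.1 µS
    assert arr.rhs[0] == 0.0


def test_setup_matrix_axial_terms_vanish_at_equal_voltage():
    tree = bs.CompartmentTree(np.array([-1, 0]), np.array([10.0, 10.0]),
                              np.array([1.0, 1.0]), np.array([0.01, 0.01]),
                              np.array([np.inf, 10.0]))
    arr = bs.SolverArrays.from_tree(tree, v_init=-65.0)
    bs.setup_matrix(arr, np.zeros(2), np.zeros(2), tree.C, 0.025)
    assert arr.rhs[0] == 0.0 and arr.rhs[1] == 0.0
    assert arr.d[0] == pytest.approx(0.01 / 0.025 + 0.1)
    assert arr.d[1] == pytest.approx(0.01 / 0.025 + 0.1)


def test_setup_matrix_requires_parent_voltage_for_subtrees():
    arr = make_arrays([-1], [-0.1], [-0.1], [0.0], [0.0], v=[-65.0],
                      has_parent=True)
    with pytest.raises(bs.SynchronizationError):
        bs.setup_matrix(arr, np.zeros(1), np.zeros(1), np.array([1.0]), 0.025)
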