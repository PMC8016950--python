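"""Kabsch superposition, Q scoring and acceptor ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from graftkit.refdata import (ACCEPTOR_SCREEN_N_QUERY, ACCEPTOR_SCREEN_R0,
                              ACCEPTOR_SCREEN_TABLE)
from graftkit.superpose import (InsufficientOverlapError, filter_by_source,
                                kabsch, q_score, rank_acceptors,
                                superpose_frameworks)
from graftkit.synth import (DecoySpec, make_decoy_library, make_fv_template,
                            random_rotation)


@pytest.fixture(scope="module")
def template():
    return make_fv_template("M3/38", seed=0)


def test_self_superposition_is_identity(template):
    res = superpose_frameworks(template, template)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0)


def test_rigid_transform_recovered_exactly(template):
    decoys, _ = make_decoy_library(template, DecoySpec(n_decoys=1, seed=3),
                                   sigmas=[0.0])
    fv, _ = decoys[0]
    res = superpose_frameworks(template, fv)
    assert res.rmsd == pytest.approx(0.0, abs=1e-6)


def test_kabsch_matches_scipy_align_vectors():
    rng = np.random.default_rng(11)
    P = rng.standard_normal((40, 3)) * 5.0
    R_true = random_rotation(rng)
    Q = P @ R_true.T + np.array([1.0, -2.0, 3.0])
    R, t, rmsd = kabsch(P, Q)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    # independent route: scipy on the centered clouds
    rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    np.testing.assert_allclose(R, rot.as_matrix(), atol=1e-8)


def test_rmsd_invariant_under_rigid_pre_transformation(template):
    rng = np.random.default_rng(5)
    decoys, _ = make_decoy_library(template, DecoySpec(n_decoys=1, seed=7),
                                   sigmas=[0.6])
    fv, _ = decoys[0]
    base = superpose_frameworks(template, fv).rmsd
    # re-jitter the target rigidly; fitted rmsd must not change
    decoys2, _ = make_decoy_library(fv, DecoySpec(n_decoys=1, seed=8), sigmas=[0.0])
    fv2, _ = decoys2[0]
    again = superpose_frameworks(template, fv2).rmsd
    assert again == pytest.approx(base, abs=1e-6)


def test_gaussian_noise_rmsd_matches_expectation(template):
    """Isotropic sigma per coordinate gives post-fit rmsd ~ sigma*sqrt(3)."""
    sigma = 0.5
    rmsds = []
    for seed in range(12):
        decoys, _ = make_decoy_library(template, DecoySpec(n_decoys=1, seed=seed),
                                       sigmas=[sigma])
        rmsds.append(superpose_frameworks(template, decoys[0][0]).rmsd)
    mean_rmsd = float(np.mean(rmsds))
    assert mean_rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.06)


def test_insufficient_overlap_raises(template):
    tiny = make_fv_template("M3/38", seed=0)
    keep_h = dict(list(sorted(tiny.heavy.items()))[:5])
    from graftkit.structures import FvStructure
    shrunk = FvStructure(heavy=keep_h, light=dict(list(sorted(tiny.light.items()))[:5]))
    with pytest.raises(InsufficientOverlapError):
        superpose_frameworks(template, shrunk)


@pytest.mark.parametrize("n, rmsd, expected", [
    (100, 0.0, 1.0),
    (100, 3.0, 0.5),     # rmsd == r0 halves the score
])
def test_q_score_closed_forms(n, rmsd, expected):
    assert q_score(n, rmsd, n, n, r0=3.0) == pytest.approx(expected)


def test_q_score_rejects_zero_counts():
    with pytest.raises(ValueError):
        q_score(0, 1.0, 10, 10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(rmsd=st.floats(0.0, 5.0), bump=st.floats(0.01, 2.0),
       n_align=st.integers(50, 220))
def test_q_monotonicity(rmsd, bump, n_align):
    q0 = q_score(n_align, rmsd, 227, 230)
    assert q_score(n_align, rmsd + bump, 227, 230) < q0
    assert q_score(n_align + 1, rmsd, 227, 230) > q0


def test_acceptor_screen_table_is_q_consistent():
    """The published screen's Q column follows from its own rmsd/N columns."""
    for (_, q, rmsd, n_align, n_res, _, _, _) in ACCEPTOR_SCREEN_TABLE:
        recomputed = q_score(n_align, rmsd, ACCEPTOR_SCREEN_N_QUERY, n_res,
                             ACCEPTOR_SCREEN_R0)
        assert recomputed == pytest.approx(q, abs=0.01)


def test_ranking_tracks_noise_level(template):
    decoys, truth = make_decoy_library(template, DecoySpec(n_decoys=3, seed=2),
                                       sigmas=[0.3, 0.6, 1.2])
    ranked, failures = rank_acceptors(template, decoys)
    assert failures == []
    sigmas = [truth[c.pdb_id]["sigma"] for c in ranked]
    assert sigmas == sorted(sigmas)


def test_query_ranks_first_against_decoy(template):
    decoys, _ = make_decoy_library(template, DecoySpec(n_decoys=1, seed=4),
                                   sigmas=[1.0])
    library = [(template, {"pdb_id": "self", "source_tag": "Rat"})] + decoys
    ranked, _ = rank_acceptors(template, library)
    assert ranked[0].pdb_id == "self"
    assert ranked[0].rmsd == pytest.approx(0.0, abs=1e-9)
    assert ranked[0].q == max(c.q for c in ranked)


def test_ranked_candidates_report_screen_columns(template):
    decoys, _ = make_decoy_library(template, DecoySpec(n_decoys=2, seed=6),
                                   sigmas=[0.4, 0.8])
    ranked, _ = rank_acceptors(template, decoys)
    for c in ranked:
        assert c.pdb_id and 0 < c.q <= 1
        assert c.rmsd >= 0 and c.n_align > 0 and c.n_residue > 0
        assert 0 <= c.seq_identity <= 100


@pytest.mark.parametrize("allowed, expected", [
    ({"Human"}, ["b", "d"]),
    (set(), []),
    ({"Human", "Humanized", "unpublished"}, ["a", "b", "c", "d"]),
])
def test_filter_by_source(allowed, expected):
    from graftkit.superpose import AcceptorCandidate
    cands = [AcceptorCandidate(p, 0.8, 1.0, 200, 220, 50, tag)
             for p, tag in [("a", "Humanized"), ("b", "Human"),
                            ("c", "unpublished"), ("d", "Human")]]
    assert [c.pdb_id for c in filter_by_source(cands, allowed)] == expected
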