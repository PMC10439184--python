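import warnings

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import pprscope as pp
from pprscope.classify import OverrideRule, RhodopsinCall
from pprscope.synthetic import mutate_sequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def nw_tuning_residue(ref, query, site, gap_open=-10.0, gap_extend=-1.0):
    """Independent affine-gap Needleman-Wunsch oracle for the mapped residue.

    Straightforward three-matrix dynamic programme with full traceback;
    returns the query symbol aligned to reference position ``site``
    (1-based), '-' when that column is a deletion in the query.
    """
    n, m = len(ref), len(query)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in query (ref consumed)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in ref (query consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[ref[i - 1], query[j - 1]]
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                           Iy[i - 1, j] + gap_open)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend,
                           Ix[i, j - 1] + gap_open)
    # traceback from the best terminal state
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    residue = None
    while i > 0 or j > 0:
        if state == 0:
            if i == site:
                residue = query[j - 1]
            prev = np.argmax([M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]])
            i, j, state = i - 1, j - 1, int(prev)
        elif state == 1:
            if i == site:
                residue = "-"
            prev = np.argmax(
                [M[i - 1, j] + (-10.0), Ix[i - 1, j] + (-1.0), Iy[i - 1, j] + (-10.0)]
            )
            i, state = i - 1, int(prev)
        else:
            prev = np.argmax(
                [M[i, j - 1] + (-10.0), Iy[i, j - 1] + (-1.0), Ix[i, j - 1] + (-10.0)]
            )
            prev = {0: 0, 1: 2, 2: 1}[int(prev)]
            j, state = j - 1, prev
    return residue


# ---------------------------------------------------------------- family


def test_family_inherited_from_best_hit(panel):
    assert pp.classify_family("AAG10475.1", panel) == ("PR", True)
    assert pp.classify_family("BAC88139.1", panel) == ("GR", True)


def test_sensory_rhodopsin_is_not_a_pump(panel):
    family, is_ppr = pp.classify_family("SYNSRI001", panel)
    assert family == "SRI" and is_ppr is False


def test_unknown_reference_rejected(panel):
    with pytest.raises(KeyError):
        pp.classify_family("NOPE.1", panel)


# ---------------------------------------------------------------- mapping


def test_identity_alignment_maps_site(panel):
    assert pp.map_tuning_site(panel.canonical.protein_seq, panel) == "L"


def test_prefix_deletion_shifts_query_coordinates(panel):
    """Deleting the first 2 residues moves the site to query position 103;
    the aligned column still returns the same letter (oracle-confirmed)."""
    canon = panel.canonical
    query = canon.protein_seq[2:]
    assert pp.map_tuning_site(query, panel) == "L"
    assert nw_tuning_residue(canon.protein_seq, query, canon.tuning_site) == "L"


def test_deleted_tuning_residue_maps_to_gap(panel):
    canon = panel.canonical
    site = canon.tuning_site
    query = canon.protein_seq[: site - 1] + canon.protein_seq[site:]
    assert pp.map_tuning_site(query, panel) == "-"
    assert nw_tuning_residue(canon.protein_seq, query, site) == "-"


@pytest.mark.parametrize("seed", range(6))
def test_mapping_agrees_with_nw_oracle_on_mutants(panel, seed):
    canon = panel.canonical
    rng = np.random.default_rng(seed)
    query = mutate_sequence(canon.protein_seq, 15.0, [canon.tuning_site], rng)
    # substitution-only mutants keep coordinates; drop a short prefix so the
    # alignment actually has to place a gap
    query = query[rng.integers(0, 4):]
    impl = pp.map_tuning_site(query, panel)
    oracle = nw_tuning_residue(canon.protein_seq, query, canon.tuning_site)
    assert impl == oracle


def test_empty_query_rejected(panel):
    with pytest.raises(ValueError):
        pp.map_tuning_site("", panel)


# ---------------------------------------------------------------- rule


@pytest.mark.parametrize(
    "residue,expected",
    [
        ("Q", ("BPR", 490.0)),
        ("q", ("BPR", 490.0)),
        ("M", ("GPR", 525.0)),
        ("L", ("GPR", 525.0)),
        ("A", ("unclassified", None)),
        ("X", ("unclassified", None)),
        ("-", ("unclassified", None)),
        (None, ("unclassified", None)),
    ],
)
def test_residue_rule(residue, expected):
    assert pp.classify_spectral(residue, "PR", True) == expected


def test_non_pump_and_non_pr_families_unclassified():
    assert pp.classify_spectral("Q", "SRI", False) == ("unclassified", None)
    assert pp.classify_spectral("Q", "XR", True) == ("unclassified", None)
    # opting in extends the rule to the xanthorhodopsin clade
    assert pp.classify_spectral("Q", "XR", True, pr_like=("PR", "XR", "GR")) == (
        "BPR",
        490.0,
    )


def test_rule_is_pure():
    first = pp.classify_spectral("M", "PR", True)
    assert all(pp.classify_spectral("M", "PR", True) == first for _ in range(5))


# ---------------------------------------------------------------- overrides


def _call(taxon, spectral, lam):
    return RhodopsinCall(
        unigene_id="u1", family="PR", is_ppr=True, tuning_residue="L",
        spectral_class=spectral, lambda_max_nm=lam, source_taxon=taxon,
    )


def test_dinoflagellate_correction_applied():
    calls = [_call("Karlodinium micrum", "GPR", 525.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the C. fusus rule finds no call here
        out = pp.apply_overrides(calls, pp.load_overrides())
    assert out[0].spectral_class == "BPR"
    assert out[0].lambda_max_nm == 490.0
    assert out[0].override_applied is True


def test_overrides_idempotent():
    calls = [_call("Ceratium fusus", "GPR", 525.0), _call("SAR11", "BPR", 490.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        once = pp.apply_overrides(calls, pp.load_overrides())
        twice = pp.apply_overrides(once, pp.load_overrides())
    assert once == twice


def test_empty_override_table_is_identity():
    calls = [_call("Karlodinium micrum", "GPR", 525.0)]
    assert pp.apply_overrides(calls, []) == calls


def test_unmatched_pattern_warns_not_errors():
    calls = [_call("Pelagibacter", "BPR", 490.0)]
    with pytest.warns(UserWarning, match="matched no call"):
        out = pp.apply_overrides(
            calls, [OverrideRule("Absent taxon", "GPR")]
        )
    assert out == calls


# ---------------------------------------------------------------- pipeline


def test_calls_invariants(calls):
    """Spectral class, wavelength and pump status stay mutually consistent."""
    lam = {"BPR": 490.0, "GPR": 525.0}
    for row in calls.itertuples(index=False):
        if row.spectral_class == "unclassified":
            assert row.lambda_max_nm is None or np.isnan(row.lambda_max_nm)
        else:
            assert row.lambda_max_nm == lam[row.spectral_class]
            assert row.is_ppr
            assert row.override_applied or row.tuning_residue in {"Q", "M", "L"}


def test_override_taxa_forced_blue(calls):
    dino = calls[
        calls["source_taxon"].fillna("").str.contains("Karlodinium|Ceratium")
    ]
    if len(dino):
        assert (dino["spectral_class"] == "BPR").all()
        assert dino["override_applied"].all()
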