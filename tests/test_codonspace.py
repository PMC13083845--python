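"""Codon-space enumeration/sampling and splice-risk profiles."""

import math

import numpy as np
import pytest

from spliceaudit import (
    CodonSpaceError,
    Peptide,
    SequenceError,
    count_encodings,
    generate_encodings,
    linker_prone_curve,
    risk_profile,
    standard_table,
)
from spliceaudit.codonspace import max_window_scores
from spliceaudit.model import encode_bases, score_window


@pytest.mark.parametrize(
    "peptide, expected",
    [("HHHHHH", 64), ("DYKDDDDK", 256), ("EQKLISEEDL", 41472)],
)
def test_count_encodings(peptide, expected):
    assert count_encodings(peptide) == expected


def test_count_matches_enumeration():
    n = count_encodings("EQK")
    encs = list(generate_encodings("EQK", mode="exhaustive"))
    assert len(encs) == len(set(encs)) == n == 2 * 2 * 2


def test_exhaustive_enumeration_small():
    encs = list(generate_encodings("HH", mode="exhaustive"))
    assert set(encs) == {"CATCAT", "CATCAC", "CACCAT", "CACCAC"}
    assert encs == sorted(encs)  # lexicographic codon order


def test_exhaustive_cap():
    with pytest.raises(CodonSpaceError, match="cap"):
        list(generate_encodings("EQKLISEEDL", mode="exhaustive", cap=1000))


def test_sampled_determinism_and_count():
    a = list(generate_encodings("GKPIPNPLLGLDST", mode="sampled", n=10, seed=1))
    b = list(generate_encodings("GKPIPNPLLGLDST", mode="sampled", n=10, seed=1))
    assert a == b and len(a) == 10
    table = standard_table()
    for enc in a:
        codons = [enc[i : i + 3] for i in range(0, len(enc), 3)]
        assert all(c in table.codons_for(aa)
                   for aa, c in zip("GKPIPNPLLGLDST", codons))
    c = list(generate_encodings("GKPIPNPLLGLDST", mode="sampled", n=10, seed=2))
    assert a != c


def test_sampled_requires_seed_and_positive_n():
    with pytest.raises(CodonSpaceError, match="seed"):
        list(generate_encodings("HH", mode="sampled", n=5))
    with pytest.raises(CodonSpaceError, match="n >= 1"):
        list(generate_encodings("HH", mode="sampled", n=0, seed=1))
    with pytest.raises(SequenceError, match="invalid amino acid"):
        count_encodings("HX")


def test_his_tag_has_no_splice_potential(model):
    # His codons (CAT/CAC) contain no G, so neither GT nor AG can occur
    prof = risk_profile("HHHHHH", model, mode="exhaustive")
    assert prof.n_evaluated == 64
    assert prof.prone5_fraction == 0.0
    assert prof.prone3_fraction == 0.0
    assert prof.prone_both_fraction == 0.0


def test_flag_tag_encodings_never_contain_gt(model):
    encs = list(generate_encodings("DYKDDDDK", mode="exhaustive"))
    assert len(encs) == 256
    assert all("GT" not in e for e in encs)  # string-level brute force
    prof = risk_profile("DYKDDDDK", model, mode="exhaustive")
    assert prof.prone5_fraction == 0.0


def test_max_window_scores_against_direct_scan(model):
    """Vectorized per-encoding maxima vs literal window-by-window scoring."""
    for enc in generate_encodings("GKPIP", mode="sampled", n=30, seed=9):
        codes = encode_bases(enc)[None, :].astype(np.intp)
        for kind, W, dinuc, off in (("donor", 9, "GT", 3),
                                    ("acceptor", 23, "AG", 18)):
            expected = -np.inf
            for s in range(len(enc) - W + 1):
                w = enc[s : s + W]
                if w[off : off + 2] == dinuc:
                    expected = max(expected, score_window(w, kind, model))
            got = max_window_scores(codes, kind, model)[0]
            assert got == expected or got == pytest.approx(expected)


def test_risk_profile_seed_determinism(model):
    kw = dict(mode="sampled", n=2000, seed=5, tau=0.0)
    a = risk_profile("GKPIPNPLLGLDST", model, **kw)
    b = risk_profile("GKPIPNPLLGLDST", model, **kw)
    assert (a.prone5_fraction, a.prone3_fraction, a.prone_both_fraction) == \
        (b.prone5_fraction, b.prone3_fraction, b.prone_both_fraction)


def test_prone_both_bounded_by_each_kind(model):
    prof = risk_profile("GKPIPNPLLGLDST", model, mode="sampled", n=5000, seed=3)
    assert prof.prone_both_fraction <= min(prof.prone5_fraction,
                                           prof.prone3_fraction)
    assert 0.0 <= prof.prone_both_fraction <= 1.0


def test_sampled_converges_to_exhaustive_truth(model):
    pep = "GGSG"  # 384 encodings, nonzero donor-prone fraction
    exact = risk_profile(pep, model, mode="exhaustive")
    assert count_encodings(pep) == 384
    n = 4000
    sampled = risk_profile(pep, model, mode="sampled", n=n, seed=17)
    for attr in ("prone5_fraction", "prone3_fraction"):
        p = getattr(exact, attr)
        se = math.sqrt(max(p * (1 - p), 1e-9) / n)
        assert abs(getattr(sampled, attr) - p) <= max(3 * se, 1e-9)


def test_flank_policy_expand_n_dominates_internal(model):
    internal = risk_profile("GKPIPNPLLGLDST", model, mode="sampled", n=3000,
                            seed=2, flank_policy="internal_only")
    expanded = risk_profile("GKPIPNPLLGLDST", model, mode="sampled", n=3000,
                            seed=2, flank_policy="expand_N")
    assert expanded.prone5_fraction >= internal.prone5_fraction
    assert expanded.prone3_fraction >= internal.prone3_fraction


def test_fixed_flanks_policy_uses_context(model):
    # 'CA' + GGT... : the flank supplies the exonic prefix of a strong donor
    prof = risk_profile("GK", model, mode="exhaustive",
                        flank_policy="fixed_flanks", flanks=("CAG", "AAGTAA"))
    base = risk_profile("GK", model, mode="exhaustive")
    assert prof.prone5_fraction >= base.prone5_fraction
    with pytest.raises(CodonSpaceError, match="flank"):
        risk_profile("GK", model, mode="exhaustive",
                     flank_policy="fixed_flanks")


def test_short_peptide_counts_as_not_prone(model):
    # 6 nt cannot host a 9-mer donor window internally
    prof = risk_profile("GS", model, mode="exhaustive")
    assert prof.prone5_fraction == 0.0 and prof.prone3_fraction == 0.0


def test_linker_prone_curve_trend(model):
    curve = linker_prone_curve("GGGGS", range(1, 4), model, n=3000, seed=1)
    assert [k for k, _, _ in curve] == [1, 2, 3]
    fracs = [f for _, f, _ in curve]
    for k, (lo, hi) in enumerate(zip(fracs, fracs[1:])):
        se = math.sqrt(max(lo * (1 - lo), 1e-9) / 3000)
        assert hi >= lo - 3 * se  # non-decreasing within sampling error
    assert fracs[-1] > fracs[0]


def test_linker_curve_gt_free_unit_and_errors(model):
    curve = linker_prone_curve("HHHHHH", range(1, 3), model, n=500, seed=1)
    assert all(f == 0.0 for _, f, _ in curve)
    with pytest.raises(CodonSpaceError):
        linker_prone_curve("GGGGS", [1], model, n=0, seed=1)
    with pytest.raises(CodonSpaceError):
        linker_prone_curve("GGGGS", [0], model, n=10, seed=1)
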