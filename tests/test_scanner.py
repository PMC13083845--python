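"""Whole-sequence window scanning, motif flagging, and audit reports."""

import numpy as np
import pytest

from spliceaudit import (
    AuditConfig,
    NucSequence,
    audit_sequence,
    find_splice_windows,
    reverse_complement,
    scan_motifs,
)
from spliceaudit.model import (
    obligate_bases,
    obligate_offsets,
    score_window,
    window_length,
)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def naive_windows(seq: NucSequence, model, tau, kinds, strands):
    """Brute-force enumeration: score every position directly."""
    L = len(seq)
    found = []
    for kind in kinds:
        W = window_length(kind)
        o1, o2 = obligate_offsets(kind)
        dinuc = obligate_bases(kind)
        for strand in strands:
            bases = seq.bases if strand == "+" else reverse_complement(seq.bases)
            ext = bases + (bases[: W - 1] if seq.is_circular else "")
            n_starts = L if seq.is_circular else max(0, len(bases) - W + 1)
            for s in range(n_starts):
                w = ext[s : s + W]
                if len(w) < W or "N" in w:
                    continue
                if w[o1] != dinuc[0] or w[o2] != dinuc[1]:
                    continue
                sc = score_window(w, kind, model)
                if sc >= tau:
                    if strand == "+":
                        start = s % L if seq.is_circular else s
                    else:
                        start = (L - (s + W)) % L if seq.is_circular else L - (s + W)
                    found.append((start, kind, strand, w, round(sc, 9)))
    return sorted(found)


def test_single_donor_window_found(model):
    seq = NucSequence("s", "AAACAGGTAAGTAAA")
    wins = find_splice_windows(seq, model, tau=0.0)
    assert len(wins) == 1
    (w,) = wins
    assert (w.kind, w.start, w.end, w.strand) == ("donor", 3, 12, "+")
    assert w.window_seq == "CAGGTAAGT"
    assert w.boundary == 6  # first intronic base (the G of GT)
    assert w.score == pytest.approx(score_window("CAGGTAAGT", "donor", model))


def test_too_short_sequence_yields_empty(model):
    assert find_splice_windows(NucSequence("s", "TTTTTTTT"), model) == []


def test_circular_origin_spanning_window(model):
    # the only GT pair spans the origin: G at position 11, T at position 0
    seq = NucSequence("c", "TAAATCCCCAGG", topology="circular")
    assert seq.bases.count("GT") == 0  # GT exists only across the origin
    wins = find_splice_windows(seq, model, tau=-100.0, kinds=("donor",),
                               strands=("+",))
    assert len(wins) == 1
    (w,) = wins
    assert (w.start, w.end) == (8, 17)  # wrapped: end > L marks the wrap
    assert w.window_seq == "CAGGTAAAT"
    # linear scan of the same bases finds nothing
    linear = NucSequence("l", seq.bases)
    assert find_splice_windows(linear, model, tau=-100.0, kinds=("donor",),
                               strands=("+",)) == []


def test_threshold_monotonicity(model):
    rng = np.random.default_rng(7)
    seq = NucSequence("r", random_seq(rng, 400))
    lo = find_splice_windows(seq, model, tau=0.0)
    hi = find_splice_windows(seq, model, tau=3.0)
    assert set(hi) <= set(lo)
    assert all(w.score >= 3.0 for w in hi)


def test_strand_symmetry(model):
    rng = np.random.default_rng(11)
    seq = NucSequence("r", random_seq(rng, 300))
    rc = seq.reverse_complement()
    minus = find_splice_windows(seq, model, tau=0.0, strands=("-",))
    plus_of_rc = find_splice_windows(rc, model, tau=0.0, strands=("+",))
    L = len(seq)
    reflected = sorted(
        (L - w.end, w.kind, w.window_seq, round(w.score, 9))
        for w in plus_of_rc
    )
    observed = sorted(
        (w.start, w.kind, w.window_seq, round(w.score, 9)) for w in minus
    )
    assert observed == reflected


def test_scanner_agrees_with_bruteforce(model):
    rng = np.random.default_rng(3)
    for topology in ("linear", "circular"):
        seq = NucSequence("r", random_seq(rng, 1000), topology)
        fast = find_splice_windows(seq, model, tau=0.0)
        got = sorted(
            (w.start, w.kind, w.strand, w.window_seq, round(w.score, 9))
            for w in fast
        )
        assert got == naive_windows(seq, model, 0.0,
                                    ("donor", "acceptor"), ("+", "-"))


def test_windows_with_n_are_skipped(model):
    seq = NucSequence("n", "AAACAGGTANGTAAA")
    assert find_splice_windows(seq, model, tau=-100.0, kinds=("donor",)) == []


def test_scan_motifs_examples():
    hits = scan_motifs(NucSequence("s", "AAGGTACCTT"))
    kpn = [h for h in hits if h.motif_name == "KpnI"]
    assert {(h.start, h.end) for h in kpn} == {(2, 8)}
    assert {h.strand for h in kpn} == {"+", "-"}  # palindromic site

    hits = scan_motifs(NucSequence("s", "CCAATAAACC"), strands=("+",))
    assert [(h.motif_name, h.start) for h in hits] == [("polyA_AATAAA", 2)]

    assert scan_motifs(NucSequence("s", "ACGTACGT"), motifs={}) == []


def test_audit_combines_windows_and_motifs(model):
    rng = np.random.default_rng(5)
    # KpnI site in a context the donor model calls a putative site
    left = "".join("AC"[i] for i in rng.integers(0, 2, size=100))
    right = "".join("AC"[i] for i in rng.integers(0, 2, size=91))
    seq = NucSequence("mcs", left + "CAGGTACCA" + right)
    assert len(seq) == 200
    report = audit_sequence(seq, model)
    kpn = [h for h in report.motif_hits if h.motif_name == "KpnI"]
    assert kpn
    donors = [w for w in report.windows if w.kind == "donor"]
    assert any(
        w.start < h.end and h.start < w.end for w in donors for h in kpn
    )
    assert report.parameters["model_checksum"] == model.checksum


def test_audit_all_a_sequence_is_silent(model):
    report = audit_sequence(NucSequence("a", "A" * 100), model)
    assert report.windows == [] and report.motif_hits == []
    assert report.summary == {}


def test_audit_report_serialization(model, tmp_path):
    seq = NucSequence("s", "AAACAGGTAAGTAAAGGTACCAAA")
    report = audit_sequence(seq, model)
    out = tmp_path / "audit.tsv"
    report.to_tsv(out)
    text = out.read_text().splitlines()
    meta = [l for l in text if l.startswith("#")]
    assert any("model_checksum" in l for l in meta)
    header = next(l for l in text if not l.startswith("#"))
    assert header.split("\t") == ["seq", "kind", "start", "end", "strand",
                                  "boundary", "window_seq", "score"]
    bed = tmp_path / "audit.bed"
    report.to_bed(bed)
    rows = [l.split("\t") for l in bed.read_text().splitlines()[1:]]
    assert all(len(r) == 6 and 0 <= int(r[4]) <= 1000 for r in rows)
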