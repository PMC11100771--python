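"""Alignment analytics: reference mapping, loops, frequencies, classes,
conservation, motifs, logos."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import structprof as sp
from structprof.seqprofile import (AA_ORDER, BMGR9_HELICES, MHOR5_HELICES,
                                   AlignmentError, AnnotatedAlignment,
                                   HelixAnnotation, class_heatmap,
                                   column_frequencies, conservation_grades,
                                   filter_sequences, logo_data, loop_lengths,
                                   loop_length_summary, motif_match,
                                   read_alignment, write_alignment)

TOY = AnnotatedAlignment(
    ids=["ref", "s1", "s2"],
    rows=["AC-DE", "AAGDE", "-CGD-"],
    reference_id="ref")


def test_colmap_from_reference_row_and_round_trip():
    # reference row "AC-DE": columns 0,1,3,4 map to residues 1..4
    assert TOY.colmap == [1, 2, None, 3, 4]
    for resnum in (1, 2, 3, 4):
        col = TOY.column_of(resnum)
        assert TOY.colmap[col] == resnum
    with pytest.raises(AlignmentError):
        TOY.column_of(99)


def test_alignment_io_round_trip(tmp_path):
    path = tmp_path / "toy.fasta"
    write_alignment(TOY, path)
    back = read_alignment(path, reference_id="ref")
    assert back.ids == TOY.ids
    assert back.rows == TOY.rows
    assert back.colmap == TOY.colmap
    with pytest.raises(AlignmentError):
        read_alignment(path, format="phylip")
    with pytest.raises(AlignmentError):
        AnnotatedAlignment(ids=["a", "b"], rows=["AC", "A"], reference_id="a")


def test_filter_sequences_boundaries_and_idempotence():
    rows = {"ref": 450, "short": 299, "lo": 300, "hi": 600, "long": 601}
    width = 700
    ids, seqs = [], []
    for name, n in rows.items():
        ids.append(name)
        seqs.append("A" * n + "-" * (width - n))
    aln = AnnotatedAlignment(ids=ids, rows=seqs, reference_id="ref")
    kept = filter_sequences(aln)
    assert kept.ids == ["ref", "lo", "hi"]
    again = filter_sequences(kept)
    assert again.ids == kept.ids          # idempotent
    # reference retained even when everything else fails the filter
    only_ref = filter_sequences(aln, min_len=440, max_len=460)
    assert only_ref.ids == ["ref"]


def test_loop_lengths_from_printed_helix_tables():
    """Direct range arithmetic on the reference helix boundary tables.

    On an ungapped reference row, shrink=0 loop lengths are simply the
    inter-boundary gaps: 10 residues between S1 (…79) and S2 (90…), and a
    single residue between S3 (…176) and S4 (178…)."""
    ref = "M" * 460
    aln = AnnotatedAlignment(ids=["bmgr9"], rows=[ref], reference_id="bmgr9")
    ll = loop_lengths(aln, BMGR9_HELICES, shrink=0)
    assert int(ll.loc["bmgr9", "S1-S2"]) == 10
    assert int(ll.loc["bmgr9", "S3-S4"]) == 1
    # shrink=1 widens every loop by two flanking positions
    ll1 = loop_lengths(aln, BMGR9_HELICES, shrink=1)
    assert int(ll1.loc["bmgr9", "S1-S2"]) == 12
    # arithmetic identity against the annotation itself, all loops
    for (na, (a0, a1)), (nb, (b0, b1)) in zip(BMGR9_HELICES.ranges,
                                              BMGR9_HELICES.ranges[1:]):
        assert int(ll.loc["bmgr9", f"{na}-{nb}"]) == b0 - a1 - 1
    ll_or = loop_lengths(
        AnnotatedAlignment(ids=["mhor5"], rows=["M" * 480], reference_id="mhor5"),
        MHOR5_HELICES, shrink=0)
    assert int(ll_or.loc["mhor5", "S1-S2"]) == 1
    assert int(ll_or.loc["mhor5", "S3-S4"]) == 38


def test_loop_lengths_recover_planted_distribution():
    spec = sp.MsaSpec(
        n_sequences=400, core_columns=30, conservation=0.9,
        loops=[{"after": 10, "max_len": 12, "ref_len": 3,
                "dist": ("choice", [3, 5, 8]), "name": "L1"},
               {"after": 20, "max_len": 16, "ref_len": 5,
                "dist": ("poisson", 6, 1), "name": "L2"}],
        seed=11)
    aln, truth = sp.simulate_msa(spec)
    helices = HelixAnnotation(ranges=(("H1", (1, 10)), ("H2", (14, 23)),
                                      ("H3", (29, 38))))
    ll = loop_lengths(aln, helices, shrink=0)
    assert np.array_equal(ll["H1-H2"].to_numpy(),
                          truth["seq_loop_lengths"]["L1"])
    assert np.array_equal(ll["H2-H3"].to_numpy(),
                          truth["seq_loop_lengths"]["L2"])
    # Poisson(6)+1 sample mean within 3 s.e. of 7
    mean = ll["H2-H3"].mean()
    se = np.sqrt(6.0) / np.sqrt(len(ll))
    assert abs(mean - 7.0) <= 3 * se
    # zero-length loops excluded from the summary
    summary = loop_length_summary(ll)
    assert (summary["n"] <= len(ll)).all()
    zeros = sp.MsaSpec(n_sequences=50, core_columns=30, conservation=0.9,
                       loops=[{"after": 10, "max_len": 6, "ref_len": 4,
                               "dist": ("choice", [0, 4]), "name": "L"}],
                       seed=3)
    aln0, truth0 = sp.simulate_msa(zeros)
    h0 = HelixAnnotation(ranges=(("H1", (1, 10)), ("H2", (15, 24))))
    ll0 = loop_lengths(aln0, h0, shrink=0)
    s0 = loop_length_summary(ll0)
    n_nonzero = int((truth0["seq_loop_lengths"]["L"] > 0).sum())
    assert int(s0.loc["H1-H2", "n"]) == n_nonzero
    assert s0.loc["H1-H2", "mean"] == pytest.approx(4.0)


def test_degenerate_shrink_raises():
    aln = AnnotatedAlignment(ids=["r"], rows=["M" * 30], reference_id="r")
    tight = HelixAnnotation(ranges=(("H1", (1, 10)), ("H2", (12, 14))))
    with pytest.raises(AlignmentError):
        loop_lengths(aln, tight, shrink=2)   # H2 inverts under the shrink


def test_column_frequencies_single_sequence_and_denominators():
    aln = AnnotatedAlignment(ids=["r", "s"], rows=["WY", "W-"], reference_id="r")
    prof = column_frequencies(aln, [1, 2])
    freq_all = prof.frequencies("all")
    assert freq_all.loc[1, "W"] == pytest.approx(1.0)
    assert freq_all.loc[2, "Y"] == pytest.approx(0.5)
    assert freq_all.loc[2, "gap"] == pytest.approx(0.5)
    freq_ng = prof.frequencies("nongap")
    assert freq_ng.loc[2, "Y"] == pytest.approx(1.0)
    # frequencies + gap fraction sum to 1 per position
    assert np.allclose(freq_all[list(AA_ORDER) + ["gap"]].sum(axis=1), 1.0,
                       atol=1e-9)


def test_class_heatmap_pure_and_planted_mixtures():
    aln = AnnotatedAlignment(ids=["r", "s"], rows=["WH", "WH"], reference_id="r")
    hm = class_heatmap(column_frequencies(aln, [1, 2]))
    assert hm.class_freq.loc[1, "aromatic"] == pytest.approx(1.0)
    # histidine counts as aromatic in the 6-class heatmap scheme
    assert hm.class_freq.loc[2, "aromatic"] == pytest.approx(1.0)
    assert hm.dominant_class == ["aromatic", "aromatic"]

    targets = [{"aromatic": 0.6, "polar": 0.4}, {"aliphatic": 0.8, "negative": 0.2}]
    spec = sp.MsaSpec(n_sequences=3000, core_columns=2, conservation=0.0,
                      class_targets=targets, seed=5)
    aln2, _ = sp.simulate_msa(spec)
    hm2 = class_heatmap(column_frequencies(aln2, [1, 2]))
    # recovered within multinomial sampling error (3 sigma ~ 0.03)
    assert hm2.class_freq.loc[1, "aromatic"] == pytest.approx(0.6, abs=0.03)
    assert hm2.class_freq.loc[2, "aliphatic"] == pytest.approx(0.8, abs=0.03)
    assert hm2.dominant_class == ["aromatic", "aliphatic"]


def test_dominant_class_counts_match_planted_pocket_composition():
    """A 21-position pocket planted with the sugar-receptor-like class mix
    (9 aromatic, 4 polar, 2 negative, 1 positive, 5 aliphatic) is summarised
    with exactly those dominant-class counts."""
    plan = (["aromatic"] * 9 + ["polar"] * 4 + ["negative"] * 2
            + ["positive"] * 1 + ["aliphatic"] * 5)
    targets = [{cls: 0.7, ("aliphatic" if cls != "aliphatic" else "polar"): 0.3}
               for cls in plan]
    spec = sp.MsaSpec(n_sequences=800, core_columns=21, conservation=0.0,
                      class_targets=targets, seed=9)
    aln, _ = sp.simulate_msa(spec)
    hm = class_heatmap(column_frequencies(aln, list(range(1, 22))))
    from collections import Counter
    counts = Counter(hm.dominant_class)
    assert counts == Counter(plan)


def test_conservation_grades_invariant_uniform_and_monotone():
    cons = np.linspace(0.0, 1.0, 45)
    spec = sp.MsaSpec(n_sequences=300, core_columns=45, conservation=cons,
                      seed=13)
    aln, _ = sp.simulate_msa(spec)
    g = conservation_grades(aln)
    assert g.grades[-1] == 9                      # invariant column
    assert g.grades[0] <= 2                       # uniform-random column
    rho = spearmanr(cons, g.scores).statistic
    assert rho > 0.95
    # grades are a monotone binning of scores
    order = np.argsort(g.scores)
    assert np.all(np.diff(np.asarray(g.grades)[order]) >= 0)


def test_frequency_outputs_permutation_invariant():
    spec = sp.MsaSpec(n_sequences=50, core_columns=10, conservation=0.5, seed=21)
    aln, _ = sp.simulate_msa(spec)
    perm = np.random.default_rng(0).permutation(len(aln.ids))
    # keep the reference first so the colmap is unchanged
    perm = [0] + [int(p) for p in perm if p != 0]
    shuffled = AnnotatedAlignment(ids=[aln.ids[i] for i in perm],
                                  rows=[aln.rows[i] for i in perm],
                                  reference_id=aln.reference_id)
    f1 = column_frequencies(aln, [1, 5, 10]).frequencies()
    f2 = column_frequencies(shuffled, [1, 5, 10]).frequencies()
    assert np.allclose(f1.to_numpy(), f2.to_numpy())


def test_motif_match_signature_and_oracle():
    seq = "X" * 0 + "AA" + "TYLVILIQF" + "AA"
    assert motif_match(seq, "TYhhhhhQF") == [(3, 11)]
    assert motif_match("AAA", "TYhhhhhQFTY") == []   # pattern longer than seq
    with pytest.raises(AlignmentError):
        motif_match(seq, "TY?")
    # brute-force sliding-window oracle on random sequences
    g = np.random.default_rng(3)
    hydro = set("AVLIPWFM")
    for _ in range(5):
        s = "".join(g.choice(list(AA_ORDER), size=80))
        pattern = "FhxQ"
        got = motif_match(s, pattern)
        expected = []
        for start in range(len(s) - 3):
            w = s[start:start + 4]
            if w[0] == "F" and w[1] in hydro and w[3] == "Q":
                expected.append((start + 1, start + 4))
        assert got == expected


def test_logo_heights():
    aln = AnnotatedAlignment(ids=["r", "a", "b", "c"],
                             rows=["WW", "WY", "WF", "WL"], reference_id="r")
    heights = logo_data(column_frequencies(aln, [1, 2]))
    # invariant column: single letter at log2(20) bits
    assert heights.loc[1, "W"] == pytest.approx(np.log2(20), abs=1e-9)
    assert heights.loc[1].drop("W").sum() == pytest.approx(0.0, abs=1e-9)
    # 4-state uniform column: hand-computed IC = log2(20) - 2 bits
    ic = np.log2(20) - 2.0
    for aa in "WYFL":
        assert heights.loc[2, aa] == pytest.approx(0.25 * ic, abs=1e-9)
    assert (heights.to_numpy() >= 0).all()
    assert heights.sum(axis=1).max() <= np.log2(20) + 1e-9
    assert heights.attrs["colors"]["H"] == "blue"    # basic in logo colours
    assert heights.attrs["colors"]["W"] == "black"


def test_helix_annotation_validation():
    with pytest.raises(AlignmentError):
        HelixAnnotation(ranges=(("A", (10, 5)),))
    with pytest.raises(AlignmentError):
        HelixAnnotation(ranges=(("A", (1, 10)), ("B", (8, 20))))
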