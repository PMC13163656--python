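"""Uncovering protocol: stepping, reference switching, thresholds, the line."""

import pytest

import geneimage as g
from geneimage.ensemble import RecognitionReport
from geneimage.uncover import LinePosition, UncoverStep

REF50 = g.ReferenceLengths(50, 50)


def make_trace(direction, start, foregrounds, backgrounds=None, switches=()):
    """Hand-build a trace whose steps recognized the given foregrounds."""
    backgrounds = backgrounds or {}
    trace = g.UncoverTrace(direction=direction, start_reference=start)
    trace.reference_history.append(start)
    ref = start
    for i, fg in enumerate(foregrounds):
        if fg in switches:
            ref = switches[fg]
            trace.reference_history.append(ref)
        bgs = backgrounds.get(fg, [])
        report = RecognitionReport(
            query_id=ref, mode="concat",
            averages={fg: 0.5, **{b: 0.05 for b in bgs}},
            threshold=0.01, recognized=[fg] + bgs,
        )
        trace.steps.append(
            UncoverStep(
                step_label=f"{i + 1}{'A' if direction == 'top_down' else 'B'}",
                reference=ref,
                teaching_set=[],
                reports={"concat": report},
                removed_after=[fg] + bgs,
            )
        )
    return trace


def chain_records(fracs, length=100):
    """Panel whose organism i shares round(fracs[i]*length) residues with org0."""
    records = []
    for i, f in enumerate(fracs):
        match = round(f * length)
        # differing residues use 'W' vs 'P' (codon distance 2 -> '-') so the
        # homologous fraction is exactly `match`/length
        seq = "P" * match + "W" * (length - match) if i else "P" * length
        records.append(g.OrganismRecord(f"o{i}", f"Org{i:02d} sp", seq[:50], seq[50:]))
    return records


def test_rooted_tree_count_examples():
    assert g.count_rooted_trees(2) == 1
    assert g.count_rooted_trees(3) == 3
    assert g.count_rooted_trees(4) == 15  # enumeration of rooted quartets
    assert float(g.count_rooted_trees(32)) == pytest.approx(1.782e42, rel=5e-4)
    with pytest.raises(ValueError):
        g.count_rooted_trees(1)


def test_count_rooted_trees_matches_recursive_enumeration():
    """(2n-3)!! equals the standard recursion count(n) = count(n-1)*(2n-3)."""
    expected = 1
    for n in range(2, 12):
        if n > 2:
            expected *= 2 * n - 3
        assert g.count_rooted_trees(n) == expected


def test_uncover_step_teaching_set_of_one(tiny_panel, tiny_ref):
    removed = {"Alpha alpha", "Beta beta"}
    step = g.uncover_step(
        tiny_panel, removed=removed, reference="Delta delta",
        seed=2, ref_lengths=tiny_ref, allow_subthreshold=True,
    )
    assert step.teaching_set == ["Gamma gamma"]
    assert step.removed_after == ["Gamma gamma"] or step.removed_after == []
    if step.removed_after:
        assert step.main_report.foreground in (None, "Gamma gamma")


def test_uncover_step_lost_recognition_flag(tiny_panel, tiny_ref):
    step = g.uncover_step(
        tiny_panel, removed={"Delta delta"}, reference="Delta delta",
        seed=2, ref_lengths=tiny_ref, threshold=1.1, allow_subthreshold=False,
    )
    assert step.lost_recognition
    assert step.removed_after == []


def test_uncover_step_empty_teaching_set_rejected(tiny_panel, tiny_ref):
    everyone = {r.latin_name for r in tiny_panel}
    with pytest.raises(ValueError, match="empty"):
        g.uncover_step(tiny_panel, removed=everyone, reference="Alpha alpha",
                       ref_lengths=tiny_ref)


def test_two_organism_panel_trivial_trace(tiny_panel, tiny_ref):
    pair = tiny_panel[:2]
    trace = g.run_uncovering(pair, "Alpha alpha", seed=4, ref_lengths=tiny_ref,
                             allow_subthreshold=True)
    assert len(trace.steps) == 1
    assert trace.steps[0].teaching_set == ["Beta beta"]


def test_trace_invariants_on_ladder(ladder_panel):
    cfg, records, truth = ladder_panel
    trace = g.run_uncovering(
        records, records[-1].latin_name, seed=17, ref_lengths=cfg.reference_lengths()
    )
    sizes = [len(s.teaching_set) for s in trace.steps]
    productive = [s for s in trace.steps if s.removed_after]
    # teaching sets shrink after every productive step
    assert sizes == sorted(sizes, reverse=True)
    removed_all = [org for s in trace.steps for org in s.removed_after]
    assert len(removed_all) == len(set(removed_all))
    assert len(trace.steps) <= len(records) * len(trace.reference_history)
    assert len(productive) >= 1


def test_threshold_marker_at_25_percent_crossing():
    fracs = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.3, 0.2, 0.1]
    records = chain_records(fracs)
    fgs = [f"Org{i:02d} sp" for i in range(1, len(fracs))]
    trace = make_trace("top_down", "Org00 sp", fgs)
    markers = g.detect_threshold_organisms(trace, records, "Org00 sp", ref_lengths=REF50)
    # crossing below 0.25 happens at Org07 (0.2); the marker is Org06 (0.3)
    assert markers.get("Org06 sp") == "**"


def test_no_marker_when_all_fractions_high():
    fracs = [1.0, 0.9, 0.8, 0.7]
    records = chain_records(fracs)
    trace = make_trace("top_down", "Org00 sp", [f"Org{i:02d} sp" for i in (1, 2, 3)])
    markers = g.detect_threshold_organisms(trace, records, "Org00 sp", ref_lengths=REF50)
    assert "**" not in markers.values()


def test_boundary_fraction_follows_ge_convention():
    # exactly 0.25 counts as >= low_frac: no drop yet
    fracs = [1.0, 0.25, 0.25]
    records = chain_records(fracs)
    trace = make_trace("top_down", "Org00 sp", ["Org01 sp", "Org02 sp"])
    markers = g.detect_threshold_organisms(trace, records, "Org00 sp", ref_lengths=REF50)
    assert "**" not in markers.values()


def test_bottom_up_marker_at_50_percent_crossing():
    # fractions vs the *top* apex rise along a bottom-up trace
    fracs = [1.0, 0.1, 0.2, 0.3, 0.4, 0.6, 0.8]
    records = chain_records(fracs)
    fgs = [f"Org{i:02d} sp" for i in range(1, 7)]
    trace = make_trace("bottom_up", "Org06 sp", fgs)
    markers = g.detect_threshold_organisms(trace, records, "Org00 sp", ref_lengths=REF50)
    # first fraction above 0.50 is Org05 (0.6); marker on Org04 (0.4)
    assert markers.get("Org04 sp") == "***"


def test_reference_switch_marker():
    fracs = [1.0, 0.9, 0.8, 0.7]
    records = chain_records(fracs)
    trace = make_trace(
        "top_down", "Org00 sp", ["Org01 sp", "Org02 sp", "Org03 sp"],
        switches={"Org02 sp": "Org01 sp"},
    )
    markers = g.detect_threshold_organisms(trace, records, "Org00 sp", ref_lengths=REF50)
    assert markers.get("Org02 sp") == "*"


def test_virtual_line_merges_without_duplicates():
    fracs = [1.0, 0.9, 0.6, 0.3, 0.15, 0.1, 0.05]
    records = chain_records(fracs)
    top = make_trace("top_down", "Org00 sp",
                     ["Org01 sp", "Org02 sp", "Org03 sp", "Org05 sp"])
    bottom = make_trace("bottom_up", "Org06 sp",
                        ["Org05 sp", "Org04 sp", "Org03 sp", "Org02 sp"])
    line, unplaced = g.build_virtual_line(top, bottom, records, ref_lengths=REF50)
    names = [p.foreground for p in line]
    assert names[0] == "Org00 sp"
    assert names[-1] == "Org06 sp"
    assert len(names) == len(set(names))
    placed = set(names) | {b for p in line for b in p.background}
    assert not (placed & set(unplaced))
    assert placed | set(unplaced) == {r.latin_name for r in records}


def test_virtual_line_two_organism_identity():
    records = chain_records([1.0, 0.9])
    top = make_trace("top_down", "Org00 sp", ["Org01 sp"])
    bottom = make_trace("bottom_up", "Org01 sp", ["Org00 sp"])
    line, unplaced = g.build_virtual_line(top, bottom, records, ref_lengths=REF50)
    assert [p.foreground for p in line] == ["Org00 sp", "Org01 sp"]
    assert unplaced == []


def test_virtual_line_attaches_backgrounds_in_brackets():
    records = chain_records([1.0, 0.9, 0.85, 0.8])
    top = make_trace(
        "top_down", "Org00 sp", ["Org01 sp", "Org03 sp"],
        backgrounds={"Org01 sp": ["Org02 sp"]},
    )
    bottom = make_trace("bottom_up", "Org03 sp", ["Org01 sp"],
                        backgrounds={"Org01 sp": ["Org02 sp"]})
    line, unplaced = g.build_virtual_line(top, bottom, records, ref_lengths=REF50)
    pos1 = next(p for p in line if p.foreground == "Org01 sp")
    assert pos1.background == ["Org02 sp"]
    assert unplaced == []
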