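"""Iterative uncovering of genetic images and the virtual line of inheritance.

One uncovering step teaches ensembles on the current teaching set (the panel
minus the reference and everything already uncovered), recognizes the
reference image, and removes whatever the *main recognition system* — the
ensemble taught on concatenated cytochrome b + COI images — recognized.
Removing recognized organisms lets previously obscured, more distant
relatives become recognizable in the next step.

When the main system recognizes nothing, the reference switches to the
earliest recognized foreground not yet used as reference (a FIFO queue), and
the run halts once that queue is exhausted. Runs started from the most
recently evolved organism ("top of evolution") and from an ancient one
("bottom") are merged, at their threshold organisms, into a single ordering:
the virtual line of inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import OrganismRecord, ReferenceLengths, build_genetic_image, fitted_sequence
from .ensemble import (
    RECOGNITION_THRESHOLD,
    RecognitionReport,
    recognize,
    teach_ensemble,
)
from .semihomology import CodonTable, count_positions

__all__ = [
    "UncoverStep",
    "UncoverTrace",
    "uncover_step",
    "run_uncovering",
    "detect_threshold_organisms",
    "build_virtual_line",
    "count_rooted_trees",
]


@dataclass(frozen=True)
class UncoverStep:
    """One teach-recognize-remove round of the uncovering process."""

    step_label: str
    reference: str
    teaching_set: list[str]
    reports: dict[str, RecognitionReport]
    removed_after: list[str]
    lost_recognition: bool = False

    @property
    def main_report(self) -> RecognitionReport:
        return self.reports["concat"]


@dataclass
class UncoverTrace:
    """Every step of one uncovering run plus bookkeeping for the line merge."""

    direction: str  # "top_down" or "bottom_up"
    start_reference: str
    steps: list[UncoverStep] = field(default_factory=list)
    reference_history: list[str] = field(default_factory=list)
    base_seed: int = 0

    def foregrounds(self) -> list[str]:
        """Foreground organism of each productive step, in step order."""
        out = []
        for s in self.steps:
            fg = s.main_report.foreground or (
                s.removed_after[0] if s.removed_after else None
            )
            if fg is not None:
                out.append(fg)
        return out

    def step_of_foreground(self, organism: str) -> UncoverStep | None:
        for s in self.steps:
            fg = s.main_report.foreground or (
                s.removed_after[0] if s.removed_after else None
            )
            if fg == organism:
                return s
        return None


def uncover_step(
    panel: list[OrganismRecord],
    removed: set[str],
    reference: str,
    modes: tuple[str, ...] = ("concat",),
    seed: int = 0,
    threshold: float = RECOGNITION_THRESHOLD,
    allow_subthreshold: bool = False,
    ref_lengths: ReferenceLengths | None = None,
    hyper: dict | None = None,
    step_label: str = "",
) -> UncoverStep:
    """Teach per-mode ensembles, recognize the reference image, remove.

    Only the ``concat`` ensemble's recognitions (or its best sub-threshold
    organism when ``allow_subthreshold``) populate ``removed_after``; other
    modes are reported but never drive the protocol.
    """
    ref_lengths = ref_lengths or ReferenceLengths()
    by_name = {r.latin_name: r for r in panel}
    if reference not in by_name:
        raise ValueError(f"reference {reference!r} not in panel")
    teaching = sorted(set(by_name) - removed - {reference})
    if not teaching:
        raise ValueError("teaching set is empty")
    exclude = (set(by_name) - set(teaching))
    reports: dict[str, RecognitionReport] = {}
    for mode in modes:
        ens = teach_ensemble(
            panel, exclude=exclude, mode=mode, base_seed=seed,
            ref=ref_lengths, hyper=hyper,
        )
        query = build_genetic_image(by_name[reference], ref_lengths, mode)
        reports[mode] = recognize(ens, query, threshold)
    main = reports["concat"]
    if main.recognized:
        removed_after = list(main.recognized)
        lost = False
    elif allow_subthreshold and main.below_threshold_top is not None:
        removed_after = [main.below_threshold_top]
        lost = False
    else:
        removed_after = []
        lost = True
    return UncoverStep(
        step_label=step_label,
        reference=reference,
        teaching_set=teaching,
        reports=reports,
        removed_after=removed_after,
        lost_recognition=lost,
    )


def run_uncovering(
    panel: list[OrganismRecord],
    start_reference: str,
    direction: str = "top_down",
    seed: int = 0,
    threshold: float = RECOGNITION_THRESHOLD,
    allow_subthreshold: bool | None = None,
    modes: tuple[str, ...] = ("concat",),
    ref_lengths: ReferenceLengths | None = None,
    hyper: dict | None = None,
) -> UncoverTrace:
    """Run uncovering to exhaustion from one starting reference.

    The reference image itself is excluded from teaching throughout. After a
    step that recognizes nothing, the next reference is popped from a FIFO
    queue of past foregrounds; the run halts when the queue is empty or the
    teaching set is exhausted. Bottom-up runs continue on the best
    sub-threshold organism by default, since recognition values against very
    distant references legitimately sit below the threshold.
    """
    if direction not in ("top_down", "bottom_up"):
        raise ValueError("direction must be 'top_down' or 'bottom_up'")
    if allow_subthreshold is None:
        allow_subthreshold = direction == "bottom_up"
    names = {r.latin_name for r in panel}
    if start_reference not in names:
        raise ValueError(f"start reference {start_reference!r} not in panel")

    trace = UncoverTrace(
        direction=direction, start_reference=start_reference, base_seed=seed
    )
    removed: set[str] = {start_reference}
    reference = start_reference
    fg_queue: list[str] = []  # FIFO of foregrounds awaiting a turn as reference
    used_refs = {start_reference}
    trace.reference_history.append(start_reference)
    suffix = "A" if direction == "top_down" else "B"
    step_no = 0
    while len(removed) < len(names):
        step_no += 1
        step = uncover_step(
            panel,
            removed=removed,
            reference=reference,
            modes=modes,
            seed=seed + 1000 * step_no,
            threshold=threshold,
            allow_subthreshold=allow_subthreshold,
            ref_lengths=ref_lengths,
            hyper=hyper,
            step_label=f"{step_no}{suffix}",
        )
        trace.steps.append(step)
        for org in step.removed_after:
            removed.add(org)
            if org not in fg_queue:
                fg_queue.append(org)
        if step.lost_recognition:
            # main system failed: switch to the earliest unused foreground
            next_ref = None
            while fg_queue:
                cand = fg_queue.pop(0)
                if cand not in used_refs:
                    next_ref = cand
                    break
            if next_ref is None:
                break
            reference = next_ref
            used_refs.add(reference)
            trace.reference_history.append(reference)
    return trace


def homolog_fractions(
    trace: UncoverTrace,
    panel: list[OrganismRecord],
    apex: str,
    ref_lengths: ReferenceLengths | None = None,
    table: CodonTable | None = None,
) -> dict[str, float]:
    """R-position fraction of each foreground vs the apex reference."""
    ref_lengths = ref_lengths or ReferenceLengths()
    by_name = {r.latin_name: r for r in panel}
    apex_seq = fitted_sequence(by_name[apex], ref_lengths, "concat")
    fracs: dict[str, float] = {}
    for org in trace.foregrounds():
        seq = fitted_sequence(by_name[org], ref_lengths, "concat")
        counts = count_positions(apex_seq, seq, table)
        fracs[org] = counts.r / counts.total
    return fracs


def detect_threshold_organisms(
    trace: UncoverTrace,
    panel: list[OrganismRecord],
    apex: str,
    low_frac: float = 0.25,
    high_frac: float = 0.50,
    ref_lengths: ReferenceLengths | None = None,
    table: CodonTable | None = None,
) -> dict[str, str]:
    """Mark threshold organisms on a trace (organism -> marker symbol).

    Top-down: the last foreground whose homologous fraction vs the apex is
    still >= ``low_frac`` before it first drops below (marker ``**``).
    Bottom-up: the last foreground with fraction <= ``high_frac`` before it
    first exceeds it (marker ``***``). The first foreground after a reference
    switch is marked ``*``.
    """
    markers: dict[str, str] = {}
    fgs = trace.foregrounds()
    if not fgs:
        return markers
    fracs = homolog_fractions(trace, panel, apex, ref_lengths, table)

    if trace.direction == "top_down":
        for i, org in enumerate(fgs):
            if fracs[org] < low_frac:
                if i > 0:
                    markers[fgs[i - 1]] = "**"
                break
    else:
        for i, org in enumerate(fgs):
            if fracs[org] > high_frac:
                if i > 0:
                    markers[fgs[i - 1]] = "***"
                break

    # first foreground recognized after each reference switch
    for switched_ref in trace.reference_history[1:]:
        for s in trace.steps:
            if s.reference == switched_ref and s.removed_after:
                fg = s.main_report.foreground or s.removed_after[0]
                markers.setdefault(fg, "*")
                break
    return markers


@dataclass(frozen=True)
class LinePosition:
    """One slot on the virtual line: a foreground plus bracketed backgrounds."""

    position: int
    foreground: str
    background: list[str]
    marker: str = ""


def build_virtual_line(
    top_trace: UncoverTrace,
    bottom_trace: UncoverTrace,
    panel: list[OrganismRecord],
    top_stop: str | None = None,
    bottom_stop: str | None = None,
    ref_lengths: ReferenceLengths | None = None,
    table: CodonTable | None = None,
) -> tuple[list[LinePosition], list[str]]:
    """Merge top-down and bottom-up traces into one ordered line.

    Position 0 is the top apex. Top-down foregrounds follow in step order up
    to ``top_stop`` (default: the trace's own ``**`` threshold organism, or
    its last foreground). Then the bottom-up side is appended reversed, from
    its ``***`` threshold organism (or ``bottom_stop``) back to its apex.
    Background organisms ride along with their step's foreground. Returns the
    line and the list of panel organisms it could not place.
    """
    markers_top = detect_threshold_organisms(
        top_trace, panel, top_trace.start_reference, ref_lengths=ref_lengths, table=table
    )
    markers_bot = detect_threshold_organisms(
        bottom_trace, panel, top_trace.start_reference, ref_lengths=ref_lengths, table=table
    )
    top_fgs = top_trace.foregrounds()
    bot_fgs = bottom_trace.foregrounds()

    if top_stop is None:
        starred = [o for o, m in markers_top.items() if m == "**"]
        top_stop = starred[0] if starred else (top_fgs[-1] if top_fgs else None)
    if bottom_stop is None:
        starred = [o for o, m in markers_bot.items() if m == "***"]
        bottom_stop = starred[0] if starred else (bot_fgs[-1] if bot_fgs else None)

    def backgrounds_of(trace: UncoverTrace, fg: str) -> list[str]:
        step = trace.step_of_foreground(fg)
        if step is None:
            return []
        return [o for o in step.removed_after if o != fg]

    line: list[LinePosition] = []
    placed: set[str] = set()

    def place(fg: str, bgs: list[str], marker: str) -> None:
        if fg in placed:
            raise ValueError(f"conflicting placement of {fg!r} on the virtual line")
        bgs = [b for b in bgs if b not in placed and b != fg]
        line.append(LinePosition(len(line), fg, bgs, marker))
        placed.add(fg)
        placed.update(bgs)

    place(top_trace.start_reference, [], "")
    for fg in top_fgs:
        if fg in placed:
            continue
        place(fg, backgrounds_of(top_trace, fg), markers_top.get(fg, ""))
        if fg == top_stop:
            break

    if bot_fgs:
        idx = bot_fgs.index(bottom_stop) if bottom_stop in bot_fgs else len(bot_fgs) - 1
        tail = bot_fgs[: idx + 1]  # bottom apex side comes last on the line
        for fg in reversed(tail):
            if fg in placed:
                continue
            place(fg, backgrounds_of(bottom_trace, fg), markers_bot.get(fg, ""))
        if bottom_trace.start_reference not in placed:
            place(bottom_trace.start_reference, [], "")

    unplaced = sorted({r.latin_name for r in panel} - placed)
    return line, unplaced


def count_rooted_trees(n: int) -> int:
    """Number of rooted binary tree topologies on n labelled leaves: (2n-3)!!."""
    if n < 2:
        raise ValueError("n must be >= 2")
    result = 1
    for odd in range(3, 2 * n - 2, 2):
        result *= odd
    return result
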