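"""FASTA and panel-configuration I/O plus report writers.

A *panel* is the set of organisms under study: a YAML file naming each
organism and the FASTA record ids of its cytochrome b and COI proteins.
Organisms are canonically ordered alphabetically by Latin name — this fixes
the network output order, so shuffled configs yield identical models.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import OrganismRecord, ReferenceLengths
from .ensemble import RecognitionReport
from .semihomology import PositionClassCounts

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_panel",
    "write_panel_config",
    "write_recognition_tsv",
    "write_counts_tsv",
    "write_trace_json",
    "read_trace_json",
]


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a protein FASTA file as (id, description, uppercased sequence)."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_panel_config(
    path: str | Path,
    records: list[OrganismRecord],
    ref: ReferenceLengths,
    code_table_id: int = 1,
    cytb_suffix: str = "_cytb",
    coi_suffix: str = "_coi",
) -> None:
    """Write a panel YAML whose record ids follow the <name><suffix> scheme."""
    doc = {
        "reference_lengths": {"cytb": ref.cytb_len, "coi": ref.coi_len},
        "code_table": code_table_id,
        "organisms": [
            {
                "common_name": r.common_name,
                "latin_name": r.latin_name,
                "cytb_record_id": f"{r.latin_name}{cytb_suffix}",
                "coi_record_id": f"{r.latin_name}{coi_suffix}",
            }
            for r in records
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_panel(
    config_path: str | Path,
    cytb_fasta: str | Path,
    coi_fasta: str | Path,
) -> tuple[list[OrganismRecord], ReferenceLengths, int]:
    """Resolve a panel YAML against its FASTA files.

    Returns records sorted alphabetically by Latin name (the canonical
    output-neuron order), the reference lengths, and the code-table id.
    Missing or duplicate record ids raise, naming the organism.
    """
    doc = yaml.safe_load(Path(config_path).read_text())
    cytb = {rid: seq for rid, _d, seq in read_fasta(cytb_fasta)}
    coi = {rid: seq for rid, _d, seq in read_fasta(coi_fasta)}
    rl = doc.get("reference_lengths", {})
    ref = ReferenceLengths(cytb_len=rl.get("cytb", 380), coi_len=rl.get("coi", 513))
    code_id = int(doc.get("code_table", 1))
    records = []
    seen: set[str] = set()
    for org in doc["organisms"]:
        latin = org["latin_name"]
        if latin in seen:
            raise ValueError(f"duplicate organism {latin!r} in panel config")
        seen.add(latin)
        try:
            cytb_seq = cytb[org["cytb_record_id"]]
        except KeyError:
            raise ValueError(
                f"organism {latin!r}: cytb record {org['cytb_record_id']!r} "
                "not found in FASTA"
            ) from None
        try:
            coi_seq = coi[org["coi_record_id"]]
        except KeyError:
            raise ValueError(
                f"organism {latin!r}: coi record {org['coi_record_id']!r} "
                "not found in FASTA"
            ) from None
        records.append(
            OrganismRecord(
                common_name=org.get("common_name", latin),
                latin_name=latin,
                cytb_seq=cytb_seq,
                coi_seq=coi_seq,
            )
        )
    records.sort(key=lambda r: r.latin_name)
    return records, ref, code_id


def write_recognition_tsv(report: RecognitionReport, path: str | Path) -> None:
    """Averages in descending order with recognized/role flags."""
    lines = ["organism\taverage\trecognized\trole"]
    ranked = sorted(report.averages.items(), key=lambda kv: (-kv[1], kv[0]))
    for org, avg in ranked:
        recognized = org in report.recognized
        if org == report.foreground:
            role = "foreground"
        elif org in report.background:
            role = "background"
        else:
            role = ""
        lines.append(f"{org}\t{avg:.6f}\t{str(recognized).lower()}\t{role}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_counts_tsv(
    rows: list[tuple[str, PositionClassCounts]], path: str | Path
) -> None:
    """Per-organism R/#/$/- counts, with the conventional bracket rendering."""
    lines = ["organism\tR\tts\ttv\tother\ttotal\tbracket"]
    for org, c in rows:
        lines.append(
            f"{org}\t{c.r}\t{c.ts}\t{c.tv}\t{c.other}\t{c.total}\t{c.as_bracket()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def trace_to_dict(trace) -> dict:
    return {
        "direction": trace.direction,
        "start_reference": trace.start_reference,
        "base_seed": trace.base_seed,
        "reference_history": trace.reference_history,
        "steps": [
            {
                "step_label": s.step_label,
                "reference": s.reference,
                "teaching_set": s.teaching_set,
                "removed_after": s.removed_after,
                "lost_recognition": s.lost_recognition,
                "reports": {m: r.to_dict() for m, r in s.reports.items()},
            }
            for s in trace.steps
        ],
    }


def write_trace_json(trace, path: str | Path) -> None:
    """Serialize an uncovering trace (seeds included) for exact replay."""
    Path(path).write_text(json.dumps(trace_to_dict(trace), indent=2))


def read_trace_json(path: str | Path):
    """Rebuild an UncoverTrace from :func:`write_trace_json` output."""
    from .uncover import UncoverStep, UncoverTrace

    doc = json.loads(Path(path).read_text())
    trace = UncoverTrace(
        direction=doc["direction"],
        start_reference=doc["start_reference"],
        base_seed=doc["base_seed"],
        reference_history=list(doc["reference_history"]),
    )
    for s in doc["steps"]:
        reports = {
            m: RecognitionReport(
                query_id=r["query_id"],
                mode=r["mode"],
                averages=r["averages"],
                threshold=r["threshold"],
                recognized=list(r["recognized"]),
                below_threshold_top=r["below_threshold_top"],
            )
            for m, r in s["reports"].items()
        }
        trace.steps.append(
            UncoverStep(
                step_label=s["step_label"],
                reference=s["reference"],
                teaching_set=list(s["teaching_set"]),
                reports=reports,
                removed_after=list(s["removed_after"]),
                lost_recognition=s["lost_recognition"],
            )
        )
    return trace
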