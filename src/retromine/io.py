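"""FASTA/GFF3/TSV input-output and coordinate-convention conversions.

Coordinates are 0-based half-open everywhere inside the package and
1-based closed in GFF3 files, converted only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import PlantedTruth


def read_fasta(path) -> dict[str, str]:
    """Ordered id -> sequence mapping; CRLF input is accepted."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Mapping[str, str], width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def to_gff_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    if end <= start:
        raise ValueError("empty interval")
    return start + 1, end


def from_gff_coords(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"invalid GFF interval {start}..{end}")
    return start - 1, end


@dataclass
class GffFeature:
    seqid: str
    source: str
    type: str
    start: int  # 1-based closed, as in the file
    end: int
    score: Optional[float]
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    def interval(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return from_gff_coords(self.start, self.end)


def _format_attributes(attributes: Mapping[str, str]) -> str:
    if not attributes:
        return "."
    return ";".join(f"{k}={v}" for k, v in attributes.items())


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    if text in (".", ""):
        return out
    for chunk in text.split(";"):
        if not chunk:
            continue
        key, sep, value = chunk.partition("=")
        if not sep:
            raise ValueError(f"malformed GFF attribute {chunk!r} at line {lineno}")
        out[key.strip()] = value.strip()
    return out


def write_gff(path, features: Iterable[GffFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            score = "." if f.score is None else f"{f.score:.3f}"
            fh.write(
                "\t".join(
                    [
                        f.seqid, f.source, f.type, str(f.start), str(f.end),
                        score, f.strand, f.phase, _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


def read_gff(path) -> list[GffFeature]:
    features: list[GffFeature] = []
    ids: set[str] = set()
    pending_parents: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF record at line {lineno}: expected 9 fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"non-integer coordinate at line {lineno}") from exc
            if end < start:
                raise ValueError(f"end < start at line {lineno}")
            score = None if fields[5] == "." else float(fields[5])
            attributes = _parse_attributes(fields[8], lineno)
            if "ID" in attributes:
                ids.add(attributes["ID"])
            if "Parent" in attributes:
                pending_parents.append((attributes["Parent"], lineno))
            features.append(
                GffFeature(fields[0], fields[1], fields[2], start, end, score,
                           fields[6], fields[7], attributes)
            )
    for parent, lineno in pending_parents:
        if parent not in ids:
            raise ValueError(f"unknown Parent={parent} at line {lineno}")
    return features


# ---------------------------------------------------------------------------
# Planted-truth GFF3
# ---------------------------------------------------------------------------


def truth_to_features(truth: Iterable[PlantedTruth]) -> list[GffFeature]:
    features: list[GffFeature] = []
    for i, rec in enumerate(truth):
        element_id = f"{rec.genome_id}.element{i}"
        s, e = to_gff_coords(rec.start, rec.end)
        features.append(
            GffFeature(
                rec.genome_id, "retromine_sim", "planted_element", s, e, None,
                rec.strand, ".",
                {"ID": element_id, "group": rec.group,
                 "divergence": f"{rec.divergence:g}"},
            )
        )
        for label, ds, de in rec.domains:
            gs, ge = to_gff_coords(ds, de)
            features.append(
                GffFeature(
                    rec.genome_id, "retromine_sim", "planted_domain", gs, ge, None,
                    rec.strand, ".",
                    {"Parent": element_id, "label": label},
                )
            )
    return features


def features_to_truth(features: Iterable[GffFeature]) -> list[PlantedTruth]:
    elements: dict[str, PlantedTruth] = {}
    domains: list[GffFeature] = []
    for f in features:
        if f.type == "planted_element":
            s, e = f.interval()
            elements[f.attributes["ID"]] = PlantedTruth(
                f.seqid, s, e, f.strand, f.attributes["group"],
                float(f.attributes.get("divergence", "nan")),
            )
        elif f.type == "planted_domain":
            domains.append(f)
    for f in domains:
        parent = elements.get(f.attributes["Parent"])
        if parent is None:
            raise ValueError(f"domain references unknown element {f.attributes['Parent']}")
        s, e = f.interval()
        parent.domains.append((f.attributes["label"], s, e))
    out = sorted(elements.values(), key=lambda t: (t.genome_id, t.start))
    for rec in out:
        rec.domains.sort(key=lambda d: (d[1], d[2], d[0]))
    return out
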