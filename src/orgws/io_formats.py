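"""Readers and writers for on-disk formats, plus shared config/logging.

Coordinate convention
---------------------
Internally every interval is **0-based, half-open** ``[start, end)``.  GFF3 (and
every human-facing report) is 1-based inclusive.  The *only* place where the two
conventions meet is :func:`gff_to_internal` / :func:`internal_to_gff`; all other
code works in internal coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("orgws")

GFF_TYPES = ("gene", "mRNA", "CDS", "exon")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# coordinate conversion: the single boundary between conventions
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive ``[start, end]`` -> 0-based half-open ``[start-1, end)``."""
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open ``[start, end)`` -> 1-based inclusive ``[start+1, end]``."""
    return start + 1, end


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    """A genomic sequence over {A,C,G,T,N}; uppercased on parse."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GffRecord:
    """One GFF3 feature line; coordinates 1-based inclusive as in the file."""

    scaffold_id: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        """Internal 0-based half-open interval."""
        return gff_to_internal(self.start, self.end)


@dataclass
class HitRecord:
    """A tabular alignment/domain hit (BLAST-like or CD-search-like evidence)."""

    query_id: str
    target_id: str
    evalue: float
    bitscore: float = 0.0
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    domain_name: str | None = None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[Scaffold]:
    """Read FASTA records, uppercased, order preserved.

    ``kind`` is informational ("nucleotide" or "protein"); both return
    :class:`Scaffold`-shaped records (id + seq).
    """
    records: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(Scaffold(id=rec.id, seq=seq))
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    seqrecs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items()) or "."


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Parse a GFF3 file into records; a trailing ``##FASTA`` section is ignored."""
    records: list[GffRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            scaf, source, ftype, start_s, end_s, score, strand, phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start or start < 1:
                raise FormatError(f"{path}:{lineno}: bad interval {start}..{end}")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            records.append(GffRecord(scaf, source, ftype, start, end, score,
                                     strand, phase, _parse_attributes(attr_s)))
    return records


def write_gff3(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write("\t".join([
                r.scaffold_id, r.source, r.type, str(r.start), str(r.end),
                r.score, r.strand, r.phase, _format_attributes(r.attributes),
            ]) + "\n")


def group_gff_genes(records: list[GffRecord]) -> dict[str, dict]:
    """Group records under their gene; CDS/exon rows sorted in transcription order.

    Returns ``{gene_id: {"gene": GffRecord|None, "cds": [...], "exon": [...],
    "strand": str, "scaffold_id": str}}``.  Transcription order means ascending
    genomic start on ``+`` and descending genomic start on ``-``.
    """
    genes: dict[str, dict] = {}

    def bucket(gid: str) -> dict:
        return genes.setdefault(gid, {"gene": None, "cds": [], "exon": [],
                                      "strand": ".", "scaffold_id": ""})

    mrna_parent: dict[str, str] = {}
    for r in records:
        if r.type == "gene":
            gid = r.attributes.get("ID", f"{r.scaffold_id}:{r.start}")
            b = bucket(gid)
            b["gene"] = r
            b["strand"] = r.strand
            b["scaffold_id"] = r.scaffold_id
        elif r.type == "mRNA":
            mid = r.attributes.get("ID", "")
            mrna_parent[mid] = r.attributes.get("Parent", mid)
    for r in records:
        if r.type in ("CDS", "exon"):
            parent = r.attributes.get("Parent", r.attributes.get("ID", ""))
            gid = parent if parent in genes else mrna_parent.get(parent, parent)
            b = bucket(gid)
            (b["cds"] if r.type == "CDS" else b["exon"]).append(r)
            if b["strand"] == ".":
                b["strand"] = r.strand
            if not b["scaffold_id"]:
                b["scaffold_id"] = r.scaffold_id
    for gid, b in genes.items():
        rev = b["strand"] == "-"
        b["cds"].sort(key=lambda r: r.start, reverse=rev)
        b["exon"].sort(key=lambda r: r.start, reverse=rev)
    return genes


# ---------------------------------------------------------------------------
# newick trees (dendropy)
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"cannot parse newick string: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------
#
# Dialects:
#   domain        : query_id <TAB> domain_name <TAB> evalue [bitscore]
#   protein_blast : 12-column blast-tabular (qid sid pident len mm go qs qe ts te ev bits)
#   topology      : protein_id <TAB> predictor <TAB> per-residue string over {M,i,o}

def read_hit_table(path: str | Path, dialect: str = "domain"):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if dialect == "domain":
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: domain dialect needs ≥3 columns")
                try:
                    ev = float(cols[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric evalue {cols[2]!r}") from exc
                bits = float(cols[3]) if len(cols) > 3 else 0.0
                rows.append(HitRecord(query_id=cols[0], target_id=cols[1],
                                      evalue=ev, bitscore=bits, domain_name=cols[1]))
            elif dialect == "protein_blast":
                if len(cols) < 12:
                    raise FormatError(f"{path}:{lineno}: blast tabular needs 12 columns")
                try:
                    ev, bits = float(cols[10]), float(cols[11])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric evalue/bitscore") from exc
                rows.append(HitRecord(
                    query_id=cols[0], target_id=cols[1], evalue=ev, bitscore=bits,
                    q_start=int(cols[6]), q_end=int(cols[7]),
                    t_start=int(cols[8]), t_end=int(cols[9])))
            elif dialect == "topology":
                if len(cols) < 3:
                    raise FormatError(f"{path}:{lineno}: topology dialect needs 3 columns")
                bad = set(cols[2]) - set("Mio")
                if bad:
                    raise FormatError(f"{path}:{lineno}: bad topology symbols {bad}")
                rows.append((cols[0], cols[1], cols[2]))
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    return rows


def write_hit_table(rows, path: str | Path, dialect: str = "domain") -> None:
    with open(path, "w") as fh:
        for r in rows:
            if dialect == "domain":
                fh.write(f"{r.query_id}\t{r.domain_name}\t{r.evalue:g}\t{r.bitscore:g}\n")
            elif dialect == "topology":
                fh.write("\t".join(r) + "\n")
            else:
                fh.write("\t".join([
                    r.query_id, r.target_id, "0.0", "0", "0", "0",
                    str(r.q_start), str(r.q_end), str(r.t_start), str(r.t_end),
                    f"{r.evalue:g}", f"{r.bitscore:g}"]) + "\n")


def topology_table_to_map(rows) -> dict[str, list[str]]:
    """Collapse topology-dialect rows to ``{protein_id: [pred1, pred2, pred3]}``."""
    out: dict[str, list[str]] = {}
    for pid, _pred, topo in rows:
        out.setdefault(pid, []).append(topo)
    return out


# ---------------------------------------------------------------------------
# motif exchange format (text PSSM blocks)
# ---------------------------------------------------------------------------
#
#   BACKGROUND <pA> <pC> <pG> <pT>
#   MOTIF <id> width=<w> nsites=<n> evalue=<e>
#   <pA> <pC> <pG> <pT>     (one line per motif position)
#   END

def write_motifs(pssms, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pssms:
            bg = " ".join(f"{x:.6f}" for x in p.background)
            fh.write(f"BACKGROUND {bg}\n")
            fh.write(f"MOTIF {p.motif_id} width={p.width} nsites={p.nsites} "
                     f"evalue={p.evalue:.6g}\n")
            for row in p.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("END\n")


def read_motifs(path: str | Path):
    from .motif_regulation import PSSM  # deferred: avoids a module cycle
    import numpy as np

    pssms = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if lines[i].startswith("BACKGROUND"):
            background = np.array([float(x) for x in lines[i].split()[1:5]])
            i += 1
        elif lines[i].startswith("MOTIF"):
            parts = lines[i].split()
            motif_id = parts[1]
            kv = dict(p.split("=", 1) for p in parts[2:])
            width, nsites = int(kv["width"]), int(kv["nsites"])
            evalue = float(kv["evalue"])
            rows = []
            i += 1
            while i < len(lines) and lines[i] != "END":
                rows.append([float(x) for x in lines[i].split()])
                i += 1
            if len(rows) != width:
                raise FormatError(f"motif {motif_id}: {len(rows)} rows for width {width}")
            i += 1  # skip END
            pssms.append(PSSM(motif_id=motif_id, probs=np.array(rows),
                              background=background.copy(), nsites=nsites,
                              evalue=evalue))
        else:
            raise FormatError(f"unexpected motif-file line: {lines[i]!r}")
    return pssms


# ---------------------------------------------------------------------------
# configuration / logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None, **overrides):
    """Build a :class:`~orgws.pipeline_driver.PipelineConfig` from YAML + overrides."""
    from .pipeline_driver import PipelineConfig

    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
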