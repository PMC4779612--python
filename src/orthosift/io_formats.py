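"""Readers, writers and run configuration.

Formats handled: multi-FASTA proteomes (one file per species), GenBank
records with CDS features (needed for composition-based HGT screening),
BLAST tabular (outfmt 6) homology hits, newick trees, relaxed-phylip
concatenated alignments and a YAML mirror of :class:`RunConfig`.

Species-id convention: a proteome's species id is the input file stem
unless an explicit ``species_of_path`` mapping is given.  FASTA headers
may additionally carry ``species=<id>`` tokens which, when present, must
agree with the file-level assignment.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("orthosift")

_PROTEIN_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]+$")
_DNA_RE = re.compile(r"^[ACGTN]+$")


class SpeciesTable:
    """Assignment of species ids to exactly two taxonomic groups."""

    def __init__(self, entries: Mapping[str, str]):
        if not entries:
            raise ValueError("species table is empty")
        groups = sorted(set(entries.values()))
        if len(groups) != 2:
            raise ValueError(
                f"exactly two groups are required, got {len(groups)}: {groups}"
            )
        self.entries: dict[str, str] = dict(entries)
        self.groups: tuple[str, str] = (groups[0], groups[1])

    def group_of(self, species: str) -> str:
        return self.entries[species]

    def species_in(self, group: str) -> list[str]:
        return sorted(s for s, g in self.entries.items() if g == group)

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesTable":
        """Two-column TSV: species id, group label. '#' lines ignored."""
        entries: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            sp, grp = parts
            if sp in entries:
                raise ValueError(f"{path}:{lineno}: duplicate species id {sp!r}")
            entries[sp] = grp
        return cls(entries)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein (optionally with its coding sequence) from one species."""

    seq_id: str
    species: str
    protein: str
    cds: str | None = None
    cds_usable: bool = False

    def __post_init__(self):
        if not self.protein:
            raise ValueError(f"{self.seq_id}: empty protein sequence")
        if not _PROTEIN_RE.match(self.protein):
            raise ValueError(f"{self.seq_id}: non-amino-acid characters in protein")


@dataclass
class RunConfig:
    """Tunable parameters of an ortholog-detection run.

    The E-value ladder runs from ``e_value_start`` down to ``e_value_end``
    by multiplying with ``10**-e_value_decrement_exponent`` each cycle
    (defaults: 1e-10 .. 1e-100 in 10 cycles).
    """

    e_value_start: float = 1e-10
    e_value_end: float = 1e-100
    e_value_decrement_exponent: int = 10
    hgt_filter_enabled: bool = False
    hgt_p_threshold: float = 0.005
    hgt_kmer_order: int = 3
    paralog_count_limit: int = 3
    min_species_per_group: int = 2
    tree_splitting_enabled: bool = True
    clustering_mode: str = "single_linkage"
    mcl_inflation: float = 1.5
    bootstrap_replicates: int = 100
    out_paralog_scope: str = "edge"
    seed: int = 0

    def __post_init__(self):
        if not (self.e_value_start > self.e_value_end > 0):
            raise ValueError("need e_value_start > e_value_end > 0")
        if self.e_value_decrement_exponent <= 0:
            raise ValueError("e_value_decrement_exponent must be positive")
        if self.min_species_per_group < 1:
            raise ValueError("min_species_per_group must be >= 1")
        if self.clustering_mode not in ("single_linkage", "markov"):
            raise ValueError(f"unknown clustering_mode {self.clustering_mode!r}")
        if self.out_paralog_scope not in ("edge", "global"):
            raise ValueError(f"unknown out_paralog_scope {self.out_paralog_scope!r}")

    def thresholds(self) -> list[float]:
        """The finite descending E-value ladder, loosest first."""
        out = []
        exp = math.log10(self.e_value_start)
        end = math.log10(self.e_value_end)
        while exp >= end - 1e-9:
            out.append(10.0 ** exp)
            exp -= self.e_value_decrement_exponent
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def _cds_usable(cds: str | None) -> bool:
    return bool(cds) and len(cds) % 3 == 0 and _DNA_RE.match(cds) is not None


def read_proteomes(
    paths: Sequence[str | Path],
    species_table: SpeciesTable,
    format: str = "fasta",
    species_of_path: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Read one proteome file per species.

    ``format="fasta"`` reads plain protein multi-FASTA; ``format="genbank_cds"``
    reads GenBank records and extracts every CDS feature (protein from the
    ``translation`` qualifier, nucleotide from the feature location), making
    the records usable for composition-based HGT screening.
    """
    if format not in ("fasta", "genbank_cds"):
        raise ValueError(f"unknown format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for p in paths:
        p = Path(p)
        species = (species_of_path or {}).get(str(p), p.stem)
        if species not in species_table:
            raise ValueError(f"species {species!r} (from {p}) not in species table")
        n_before = len(records)
        if format == "fasta":
            for rec in SeqIO.parse(str(p), "fasta"):
                _add_record(records, seen, rec.id, species, str(rec.seq).upper(), None)
        else:
            for gb in SeqIO.parse(str(p), "genbank"):
                for feat in gb.features:
                    if feat.type != "CDS":
                        continue
                    quals = feat.qualifiers
                    seq_id = (
                        quals.get("protein_id", quals.get("locus_tag", ["?"]))[0]
                    )
                    prot = quals.get("translation", [None])[0]
                    if prot is None:
                        continue
                    cds = str(feat.extract(gb.seq)).upper()
                    _add_record(records, seen, seq_id, species, prot.upper(), cds)
        if len(records) == n_before:
            raise ValueError(f"no sequences read from {p}")
    return records


def _add_record(records, seen, seq_id, species, protein, cds):
    if seq_id in seen:
        raise ValueError(f"duplicate seq_id {seq_id!r}")
    seen.add(seq_id)
    usable = _cds_usable(cds)
    if cds is not None and not usable:
        logger.warning(
            "%s: CDS unusable for composition screening "
            "(length %d not divisible by 3 or non-ACGT characters)",
            seq_id, len(cds),
        )
    records.append(
        SequenceRecord(seq_id=seq_id, species=species, protein=protein.rstrip("*"),
                       cds=cds, cds_usable=usable)
    )


def parse_blast_tabular(path: str | Path, known_ids: Iterable[str] | None = None):
    """Parse 12-column BLAST tabular (outfmt 6) into a :class:`HitTable`.

    Self-hits are discarded; per-query lists are sorted by ascending
    E-value with ties broken by descending bit score then subject id.
    Extra trailing columns are ignored with a warning.
    """
    from .homology import Hit, HitTable

    known = set(known_ids) if known_ids is not None else None
    hits: dict[str, list[Hit]] = {}
    warned_extra = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
        if len(cols) > 12 and not warned_extra:
            logger.warning("%s:%d: extra columns beyond 12 are ignored", path, lineno)
            warned_extra = True
        query, subject = cols[0], cols[1]
        try:
            evalue = float(cols[10])
            bits = float(cols[11])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
        if known is not None and (query not in known or subject not in known):
            bad = query if query not in known else subject
            raise ValueError(f"{path}:{lineno}: unknown seq_id {bad!r}")
        if query == subject:
            continue
        hits.setdefault(query, []).append(
            Hit(query=query, subject=subject, score_bits=bits,
                evalue=max(evalue, 1e-300))
        )
    table = HitTable(search_space=0)
    for q, lst in hits.items():
        table.hits[q] = sorted(lst, key=lambda h: (h.evalue, -h.score_bits, h.subject))
    return table


def write_ortholog_outputs(ortholog_set, mode: str, out_dir: str | Path,
                           records_by_id: Mapping[str, SequenceRecord]) -> list[Path]:
    """Write accepted ortholog groups as FASTA.

    ``per_file_fasta`` emits ``ortholog_0001.fasta`` ...; ``single_file_fasta``
    emits one ``orthologs.fasta`` whose groups are separated by
    ``#ortholog_NNNN`` delimiter lines.  Headers carry seq id, species and
    group.
    """
    if mode not in ("per_file_fasta", "single_file_fasta"):
        raise ValueError(f"unknown mode {mode!r}")
    if not ortholog_set.groups:
        raise ValueError("ortholog set is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fasta_block(group) -> str:
        lines = []
        for sid in sorted(group.members):
            rec = records_by_id[sid]
            grp = ortholog_set.species_table.group_of(rec.species)
            lines.append(f">{sid} species={rec.species} group={grp}")
            lines.append(rec.protein)
        return "\n".join(lines) + "\n"

    if mode == "per_file_fasta":
        for i, group in enumerate(ortholog_set.groups, 1):
            path = out_dir / f"ortholog_{i:04d}.fasta"
            path.write_text(fasta_block(group))
            written.append(path)
    else:
        path = out_dir / "orthologs.fasta"
        chunks = [
            f"#ortholog_{i:04d}\n" + fasta_block(group)
            for i, group in enumerate(ortholog_set.groups, 1)
        ]
        path.write_text("".join(chunks))
        written.append(path)
    return written


def read_single_file_fasta(path: str | Path) -> list[set[str]]:
    """Re-read the single-file ortholog output; returns member-id sets."""
    groups: list[set[str]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#ortholog_"):
            groups.append(set())
        elif line.startswith(">"):
            groups[-1].add(line[1:].split()[0])
    return groups


def write_phylip_concatenation(concat, path: str | Path) -> None:
    """Relaxed-phylip export (long names allowed, '-' for missing data)."""
    rows = concat.rows
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"unequal concatenated row lengths: {sorted(lengths)}")
    n_sites = lengths.pop()
    lines = [f"{len(rows)} {n_sites}"]
    for name in sorted(rows):
        lines.append(f"{name}  {rows[name]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> dict[str, str]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n_taxa, n_sites = (int(x) for x in lines[0].split())
    rows: dict[str, str] = {}
    for line in lines[1 : 1 + n_taxa]:
        name, seq = line.split(None, 1)
        rows[name] = seq.strip()
        if len(rows[name]) != n_sites:
            raise ValueError(f"{name}: expected {n_sites} sites")
    return rows


def newick_io(tree_or_text, direction: str):
    """Convert between :class:`~orthosift.phylo.GeneTree` and newick text."""
    from . import phylo

    if direction == "write":
        return phylo.to_newick(tree_or_text)
    if direction == "read":
        return phylo.from_newick(tree_or_text)
    raise ValueError(f"direction must be 'read' or 'write', got {direction!r}")
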