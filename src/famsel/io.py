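"""Readers and writers for the package's tabular and sequence formats.

Genotype tables are TSV with header
``family_id individual_id role breed sex DRB1 DQA1 DQB1``; each locus column
holds an unordered allele pair ``x/y`` (``.`` = missing).  Allele sequences
are FASTA with record ids ``DLA-<LOCUS>*<NAME>`` (e.g. ``DLA-DRB1*01501``).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .types import (AlleleCall, AlleleSequence, GenotypeRecord, Locus, Role,
                    COMPOSITE_DQB1)

__all__ = [
    "read_genotype_table", "write_genotype_table", "read_allele_fasta",
    "write_allele_fasta", "translate_exon2", "write_validation_report",
]

GENOTYPE_COLUMNS = ["family_id", "individual_id", "role", "breed", "sex",
                    "DRB1", "DQA1", "DQB1"]
MISSING = "."

#: DQB1 allele names that denote the duplicated-locus composite allele.
COMPOSITE_NAMES = frozenset({COMPOSITE_DQB1})


def _parse_pair(field: str, locus: Locus, row_no: int):
    if field == MISSING or field == "":
        return None
    parts = field.split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(
            f"row {row_no}: malformed {locus.value} genotype {field!r} "
            "(expected 'allele1/allele2' or '.')")
    calls = tuple(
        AlleleCall(locus, p,
                   composite=(locus is Locus.DQB1 and p in COMPOSITE_NAMES))
        for p in parts)
    return calls


def read_genotype_table(path, *, delimiter: str = "\t") -> list:
    """Parse a genotype TSV into :class:`GenotypeRecord` objects.

    Missing loci are absent from ``record.genotype``; allele pairs come back
    lexicographically sorted.  Raises :class:`ValueError` naming the offending
    row for malformed input, unknown columns, or a family with two dams/sires.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        if header != GENOTYPE_COLUMNS:
            unknown = [c for c in header if c not in GENOTYPE_COLUMNS]
            raise ValueError(
                f"unexpected genotype table header {header!r}"
                + (f"; unknown columns {unknown}" if unknown else ""))
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != len(GENOTYPE_COLUMNS):
                raise ValueError(
                    f"row {row_no}: expected {len(GENOTYPE_COLUMNS)} fields, "
                    f"got {len(fields)}")
            fam, ind, role, breed, sex = fields[:5]
            try:
                role_e = Role(role)
            except ValueError:
                raise ValueError(f"row {row_no}: unknown role {role!r}") from None
            genotype = {}
            for locus, field in zip(Locus, fields[5:]):
                pair = _parse_pair(field, locus, row_no)
                if pair is not None:
                    genotype[locus] = pair
            records.append(GenotypeRecord(
                individual_id=ind, family_id=fam, role=role_e, breed=breed,
                sex=(sex if sex not in (MISSING, "") else None),
                genotype=genotype))
    _check_single_parents(records)
    return records


def _check_single_parents(records: Iterable) -> None:
    seen = {}
    for rec in records:
        if rec.role is Role.OFFSPRING:
            continue
        key = (rec.family_id, rec.role)
        prev = seen.get(key)
        if prev is not None and prev != rec.individual_id:
            raise ValueError(
                f"family {rec.family_id} has two {rec.role.value}s: "
                f"{prev}, {rec.individual_id}")
        seen[key] = rec.individual_id


def write_genotype_table(records, path, *, delimiter: str = "\t") -> None:
    """Inverse of :func:`read_genotype_table` (canonical allele order)."""
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(GENOTYPE_COLUMNS) + "\n")
        for rec in records:
            fields = [rec.family_id, rec.individual_id, rec.role.value,
                      rec.breed, rec.sex if rec.sex is not None else MISSING]
            for locus in Locus:
                pair = rec.genotype.get(locus)
                fields.append(MISSING if pair is None
                              else f"{pair[0].name}/{pair[1].name}")
            fh.write(delimiter.join(fields) + "\n")


# ---------------------------------------------------------------------------
# sequences

def translate_exon2(nt_seq: str, frame_offset: int = 0) -> str:
    """Translate an exon-2 nucleotide sequence with the standard code.

    ``frame_offset`` (0, 1 or 2) skips leading bases before the first codon;
    trailing bases that do not fill a codon are dropped.  Codons containing N
    translate to X.  An internal stop raises :class:`ValueError` naming the
    codon index (0-based).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = nt_seq[frame_offset:].upper()
    if bad := set(seq) - set("ACGTN"):
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    seq = seq[: len(seq) - len(seq) % 3]
    aa = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            aa.append("X")
            continue
        res = str(Seq(codon).translate())
        if res == "*":
            raise ValueError(f"internal stop codon at codon index {i // 3}")
        aa.append(res)
    return "".join(aa)


def _parse_fasta_id(rec_id: str):
    # "DLA-DRB1*01501" -> (Locus.DRB1, "01501")
    name = rec_id.split()[0]
    if name.startswith("DLA-"):
        name = name[4:]
    if "*" not in name:
        raise ValueError(f"cannot parse allele id {rec_id!r} "
                         "(expected 'DLA-LOCUS*NAME')")
    locus_s, allele = name.split("*", 1)
    return Locus(locus_s), allele


def read_allele_fasta(path, *, alphabet: str = "aa",
                      frame_offset: int = 0) -> dict:
    """Read allele exon-2 sequences from FASTA.

    ``alphabet`` is ``"aa"`` (records are protein) or ``"nt"`` (records are
    nucleotide and get translated with ``frame_offset``).  Returns a dict
    ``(Locus, allele_name) -> AlleleSequence``.
    """
    if alphabet not in ("aa", "nt"):
        raise ValueError("alphabet must be 'aa' or 'nt'")
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        locus, name = _parse_fasta_id(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "nt":
            aa = translate_exon2(seq, frame_offset)
            entry = AlleleSequence(AlleleCall(locus, name), aa_seq=aa,
                                   nt_seq=seq)
        else:
            entry = AlleleSequence(AlleleCall(locus, name), aa_seq=seq)
        out[(locus, name)] = entry
    return out


def write_allele_fasta(sequences, path, *, alphabet: str = "aa") -> None:
    with Path(path).open("w") as fh:
        for seq in sequences:
            body = seq.aa_seq if alphabet == "aa" else (seq.nt_seq or "")
            fh.write(f">DLA-{seq.allele.locus.value}*{seq.allele.name}\n")
            fh.write(body + "\n")


def write_validation_report(flags, path) -> None:
    """TSV of flagged offspring/locus pairs from Mendelian validation."""
    with Path(path).open("w") as fh:
        fh.write("family_id\tindividual_id\tlocus\tstatus\n")
        for family_id, individual_id, locus, status in flags:
            fh.write(f"{family_id}\t{individual_id}\t{locus.value}\t{status}\n")
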