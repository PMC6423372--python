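"""Readers and writers for the on-disk formats.

Conventions: GFF3 coordinates are 1-based inclusive; FASTA wraps at 60
columns; counts are TSV with a ``gene_id`` and ``length_bp`` column
followed by one column per library; plates are CSV with well metadata
followed by one fluorescence column per cycle; ground truth and summaries
are JSON. Readers validate and reject rather than silently coerce, and
every writer produces files its paired reader accepts.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assays import PlateRun, Well
from .divergence import LtrAnnotation
from .errors import ParseError, ValidationError
from .homoeology import MatchPair, SyntenyBlock, TandemArray
from .model import AlignedPair, Chromosome, ExpressionMatrix, Gene, GenomeLayout, Library
from .synthio import SyntheticTruth

__all__ = [
    "read_gff3", "write_gff3",
    "read_counts", "write_counts",
    "read_libraries", "write_libraries",
    "read_plate", "write_plate",
    "read_ltr_pairs_fasta", "write_ltr_pairs_fasta",
    "read_match_pairs", "write_edges",
    "read_ltr_intervals",
    "read_truth", "write_truth",
    "load_config",
]


# ---------------------------------------------------------------------------
# GFF3


def _fmt_attrs(**kwargs) -> str:
    return ";".join(f"{k}={v}" for k, v in kwargs.items() if v is not None)


def _parse_attrs(text: str, path, lineno: int) -> dict:
    attrs = {}
    for field in text.strip().split(";"):
        if not field:
            continue
        if "=" not in field:
            raise ParseError(f"{path}:{lineno}: malformed attribute {field!r}")
        k, v = field.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def write_gff3(layout: GenomeLayout, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        by_chrom = layout.genes_by_chromosome()
        for chrom in layout.chromosomes:
            fh.write(f"##sequence-region {chrom.chrom_id} 1 {chrom.length_bp}\n")
        for chrom in layout.chromosomes:
            attrs = _fmt_attrs(ID=chrom.chrom_id, quartet_id=chrom.quartet_id,
                               copy_index=chrom.copy_index)
            fh.write(f"{chrom.chrom_id}\tpolyploidkit\tchromosome\t1\t"
                     f"{chrom.length_bp}\t.\t.\t.\t{attrs}\n")
            for g in by_chrom[chrom.chrom_id]:
                attrs = _fmt_attrs(ID=g.gene_id, family=g.family)
                fh.write(f"{g.chrom_id}\tpolyploidkit\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


def read_gff3(path) -> GenomeLayout:
    path = Path(path)
    chromosomes: list[Chromosome] = []
    raw_genes: list[tuple] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = _parse_attrs(attr_text, path, lineno)
            if ftype == "chromosome":
                try:
                    chromosomes.append(Chromosome(
                        chrom_id=attrs.get("ID", chrom),
                        quartet_id=int(attrs["quartet_id"]),
                        copy_index=int(attrs["copy_index"]),
                        length_bp=end_i))
                except KeyError as e:
                    raise ParseError(
                        f"{path}:{lineno}: chromosome missing attribute {e}") from None
            elif ftype == "gene":
                if "ID" not in attrs:
                    raise ParseError(f"{path}:{lineno}: gene without ID attribute")
                gid = attrs["ID"]
                if gid in seen_ids:
                    raise ValidationError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                seen_ids.add(gid)
                raw_genes.append((gid, chrom, start_i, end_i, strand,
                                  attrs.get("family", gid)))
    genes: list[Gene] = []
    by_chrom: dict[str, list[tuple]] = {}
    for rec in raw_genes:
        by_chrom.setdefault(rec[1], []).append(rec)
    for chrom_id, recs in by_chrom.items():
        recs.sort(key=lambda r: r[2])
        for rank, (gid, chrom, start, end, strand, family) in enumerate(recs, start=1):
            genes.append(Gene(gid, chrom, start, end, strand, family, rank))
    return GenomeLayout(chromosomes=chromosomes, genes=genes)


# ---------------------------------------------------------------------------
# Counts and library metadata


def write_counts(matrix: ExpressionMatrix, path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length_bp", matrix.gene_length_bp)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_libraries(libraries: list[Library], path) -> None:
    pd.DataFrame([{"library_id": l.library_id, "tissue": l.tissue,
                   "fruit": l.fruit} for l in libraries]).to_csv(path, sep="\t", index=False)


def read_libraries(path) -> list[Library]:
    df = pd.read_csv(path, sep="\t")
    for col in ("library_id", "fruit"):
        if col not in df.columns:
            raise ParseError(f"{path}: library table missing column {col!r}")
    return [Library(library_id=str(r.library_id), tissue=str(getattr(r, "tissue", "")),
                    fruit=bool(r.fruit)) for r in df.itertuples()]


def read_counts(path, libraries_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length_bp" not in df.columns:
        raise ParseError(f"{path}: counts table missing 'length_bp' column")
    lengths = df.pop("length_bp")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count values")
    neg = np.argwhere(vals < 0)
    if neg.size:
        r, c = neg[0]
        raise ValidationError(
            f"{path}: negative count for gene {df.index[r]!r} in library {df.columns[c]!r}")
    frac = np.argwhere(np.mod(vals, 1) != 0)
    if frac.size:
        r, c = frac[0]
        raise ValidationError(
            f"{path}: non-integer count for gene {df.index[r]!r} in library {df.columns[c]!r}")
    if libraries_path is not None:
        libraries = read_libraries(libraries_path)
        if [l.library_id for l in libraries] != list(df.columns):
            raise ValidationError(f"{path}: library metadata does not match count columns")
    else:
        libraries = [Library(library_id=str(c)) for c in df.columns]
    return ExpressionMatrix(counts=df.astype(np.int64), gene_length_bp=lengths,
                            libraries=libraries)


# ---------------------------------------------------------------------------
# Plates


def write_plate(run: PlateRun, path) -> None:
    n_cycles = max(len(w.fluorescence) for w in run.wells)
    rows = []
    for w in run.wells:
        row = {"well": w.well_id, "role": w.role, "sample_id": w.sample_id or "",
               "concentration_uM": "" if w.concentration_uM is None else w.concentration_uM,
               "dilution": w.dilution,
               "mass_mg": "" if w.mass_mg is None else w.mass_mg}
        for i in range(n_cycles):
            row[f"f{i + 1:03d}"] = w.fluorescence[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate(path) -> PlateRun:
    df = pd.read_csv(path)
    for col in ("well", "role"):
        if col not in df.columns:
            raise ParseError(f"{path}: plate CSV missing column {col!r}")
    fcols = sorted(c for c in df.columns if c.startswith("f") and c[1:].isdigit())
    if len(fcols) < 2:
        raise ParseError(f"{path}: plate CSV needs >= 2 fluorescence columns")
    wells = []
    for r in df.itertuples():
        conc = getattr(r, "concentration_uM", None)
        conc = None if conc is None or pd.isna(conc) or conc == "" else float(conc)
        mass = getattr(r, "mass_mg", None)
        mass = None if mass is None or pd.isna(mass) or mass == "" else float(mass)
        dil = getattr(r, "dilution", 1.0)
        dil = 1.0 if pd.isna(dil) else float(dil)
        sid = getattr(r, "sample_id", None)
        sid = None if sid is None or pd.isna(sid) or sid == "" else str(sid)
        wells.append(Well(well_id=str(r.well), role=str(r.role),
                          fluorescence=np.array([getattr(r, c) for c in fcols], dtype=float),
                          concentration_uM=conc, dilution=dil, mass_mg=mass,
                          sample_id=sid))
    return PlateRun(wells=wells)


# ---------------------------------------------------------------------------
# LTR pairs as FASTA (two records per pair: <label>/a, <label>/b)


def write_ltr_pairs_fasta(pairs: list[AlignedPair], path) -> None:
    records = []
    for i, p in enumerate(pairs):
        label = p.label or f"pair{i:04d}"
        records.append(SeqRecord(Seq(p.seq_a), id=f"{label}/a", description=""))
        records.append(SeqRecord(Seq(p.seq_b), id=f"{label}/b", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_ltr_pairs_fasta(path) -> list[AlignedPair]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ParseError(f"{path}: odd number of FASTA records; expected pairs")
    pairs = []
    for a, b in zip(records[::2], records[1::2]):
        label_a = a.id.rsplit("/", 1)[0]
        label_b = b.id.rsplit("/", 1)[0]
        if label_a != label_b:
            raise ParseError(f"{path}: record ids {a.id!r} and {b.id!r} are not a pair")
        pairs.append(AlignedPair(seq_a=str(a.seq), seq_b=str(b.seq), label=label_a))
    return pairs


# ---------------------------------------------------------------------------
# Match pairs, edges, blocks, arrays


def read_match_pairs(path, layout: GenomeLayout) -> list[MatchPair]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ParseError(f"{path}: match table missing column {col!r}")
    pairs = []
    for r in df.itertuples():
        a = layout.gene(str(r.gene_a))
        b = layout.gene(str(r.gene_b))
        pairs.append(MatchPair(a.gene_id, b.gene_id, a.chrom_id, b.chrom_id,
                               a.rank, b.rank, float(getattr(r, "score", 1.0))))
    return pairs


def write_match_pairs(pairs: list[MatchPair], path) -> None:
    pd.DataFrame([{"gene_a": p.gene_a, "gene_b": p.gene_b, "score": p.score}
                  for p in pairs]).to_csv(path, sep="\t", index=False)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_blocks(blocks: list[SyntenyBlock], path) -> None:
    rows = []
    for i, b in enumerate(blocks, start=1):
        rows.append({"block_id": i, "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                     "orientation": "inverted" if b.inverted else "same",
                     "n_pairs": b.n_pairs,
                     "pairs": ",".join(f"{p.gene_a}|{p.gene_b}" for p in b.pairs)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tandem(arrays: list[TandemArray], path) -> None:
    pd.DataFrame([{"chrom": a.chrom, "family": a.family, "size": a.size,
                   "members": ",".join(a.members)} for a in arrays]) \
        .to_csv(path, sep="\t", index=False)


def read_ltr_intervals(path, chrom_lengths: dict[str, int] | None = None) -> LtrAnnotation:
    """BED-like TSV: chrom, start, end, intact (0/1), identity (optional)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end", "intact"):
        if col not in df.columns:
            raise ParseError(f"{path}: LTR interval table missing column {col!r}")
    df["intact"] = df["intact"].astype(bool)
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom")["end"].max().astype(int).to_dict()
    return LtrAnnotation(intervals=df, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# Truth / config / JSON helpers


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_truth(path) -> SyntheticTruth:
    raw = json.loads(Path(path).read_text())
    return SyntheticTruth(
        dominant_copy={int(q): {k: int(v) for k, v in d.items()}
                       for q, d in raw.get("dominant_copy", {}).items()},
        tandem_members=raw.get("tandem_members", {}),
        gene_family=raw.get("gene_family", {}),
        ltr_true_d=raw.get("ltr_true_d", {}),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top-level YAML must be a mapping")
    return cfg
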