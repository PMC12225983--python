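"""Readers and writers for the plain-text formats the analysis exchanges.

Formats:

* FASTA — one record per organelle genome (Biopython ``SeqIO``).
* GFF3 subset — feature types CDS, rRNA, tRNA, intron; multi-segment CDS
  records share an ``ID``/``Parent`` attribute and are concatenated in
  file order.
* BED — 3-column (0-based half-open) for excluded repeats; 4-column with
  a copy count for the numt map.
* pileup TSV — per-line, per-site allele counts
  (``genome  pos  ref  depth  A  C  G  T  indels``), where ``indels`` is
  ``.`` or a ``;``-joined list of ``ins:SEQ:count`` / ``del:LEN:count``.
* line-metadata, truth-ledger, read-stats TSVs and a minimal VCF-like
  variant file.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomes import AnnotationRecord, ReferenceSet

PILEUP_COLUMNS = ["genome", "pos", "ref", "depth", "A", "C", "G", "T", "indels"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based half-open in memory)

def write_bed(path: str | Path, intervals: list[tuple], chrom: str) -> None:
    """3-column for (start, end) tuples, 4-column for (start, end, value)."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end = iv[0], iv[1]
            extra = "".join(f"\t{v}" for v in iv[2:])
            fh.write(f"{chrom}\t{start - 1}\t{end - 1}{extra}\n")


def read_bed(path: str | Path) -> dict[str, list[tuple]]:
    out: dict[str, list[tuple]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            iv = (start0 + 1, end0 + 1) + tuple(int(v) for v in fields[3:])
            out.setdefault(chrom, []).append(iv)
    return out


# ---------------------------------------------------------------------------
# GFF3 subset

def write_gff3(path: str | Path, annotation: dict[str, list[AnnotationRecord]]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome, records in annotation.items():
            for i, rec in enumerate(records):
                rid = rec.gene_id or f"{genome}.{rec.feature}.{i}"
                for start, end in rec.segments:
                    fh.write(
                        f"{genome}\tsim\t{rec.feature}\t{start}\t{end}\t.\t"
                        f"{rec.strand}\t.\tID={rid}\n"
                    )


def read_gff3(path: str | Path) -> dict[str, list[AnnotationRecord]]:
    """Parse the subset; rows sharing (genome, feature, ID) become one
    multi-segment record with segments in file order."""
    keyed: dict[tuple, AnnotationRecord] = {}
    order: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            genome, feature, start, end, strand, attrs = (
                f[0], f[2], int(f[3]), int(f[4]), f[6], f[8],
            )
            if feature not in ("CDS", "rRNA", "tRNA", "intron"):
                continue
            m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            rid = m.group(1) if m else f"{genome}:{start}-{end}"
            key = (genome, feature, rid)
            if key in keyed:
                keyed[key].segments.append((start, end))
            else:
                rec = AnnotationRecord.__new__(AnnotationRecord)
                rec.feature, rec.segments, rec.strand, rec.gene_id = (
                    feature, [(start, end)], strand, rid,
                )
                keyed[key] = rec
                order.append(key)
    out: dict[str, list[AnnotationRecord]] = {}
    for key in order:
        rec = keyed[key]
        # run validation now that all segments are collected
        validated = AnnotationRecord(
            feature=rec.feature, segments=rec.segments,
            strand=rec.strand, gene_id=rec.gene_id,
        )
        out.setdefault(key[0], []).append(validated)
    return out


# ---------------------------------------------------------------------------
# pileup count tables

def format_indel_cell(indels: dict[str, int]) -> str:
    if not indels:
        return "."
    parts = []
    for allele in sorted(indels):
        kind, payload = allele.split(":", 1)
        parts.append(f"{kind}:{payload}:{indels[allele]}")
    return ";".join(parts)


def parse_indel_cell(cell: str) -> dict[str, int]:
    if cell in (".", ""):
        return {}
    out = {}
    for part in cell.split(";"):
        kind, payload, count = part.rsplit(":", 2) if part.count(":") > 2 else part.split(":")
        out[f"{kind}:{payload}"] = int(count)
    return out


def write_pileup(path: str | Path, table) -> None:
    """Write a SiteCountTable (see calling module) as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        bases = table.base_counts
        for i, pos in enumerate(table.pos):
            cell = format_indel_cell(table.indels.get(int(pos), {}))
            fh.write(
                f"{table.genome_id}\t{pos}\t{table.ref_bases[i]}\t{table.depth[i]}\t"
                f"{bases[i, 0]}\t{bases[i, 1]}\t{bases[i, 2]}\t{bases[i, 3]}\t{cell}\n"
            )


def read_pileup(path: str | Path, line_id: str):
    from .calling import SiteCountTable  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"indels": str}, keep_default_na=False)
    genome_id = df["genome"].iloc[0]
    indels = {
        int(pos): parse_indel_cell(cell)
        for pos, cell in zip(df["pos"], df["indels"])
        if cell not in (".", "")
    }
    return SiteCountTable(
        line_id=line_id,
        genome_id=genome_id,
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref_bases="".join(df["ref"]),
        depth=df["depth"].to_numpy(dtype=np.int64),
        base_counts=df[["A", "C", "G", "T"]].to_numpy(dtype=np.int64),
        indels=indels,
    )


# ---------------------------------------------------------------------------
# fixture bundles

def read_reference_bundle(fixture_dir: str | Path) -> dict:
    """Rebuild the ReferenceSet pair from a written fixture directory."""
    import yaml

    from .genomes import ReferenceSet

    fixture_dir = Path(fixture_dir)
    seqs = read_fasta(fixture_dir / "reference.fasta")
    annotation = (
        read_gff3(fixture_dir / "annotation.gff3")
        if (fixture_dir / "annotation.gff3").exists()
        else {}
    )
    nuclear_size = 0
    cfg_path = fixture_dir / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            nuclear_size = int(yaml.safe_load(fh).get("nuclear_genome_size", 0))
    refs = {}
    for gid, seq in seqs.items():
        excluded_path = fixture_dir / f"{gid}.excluded.bed"
        numt_path = fixture_dir / f"{gid}.numt.bed"
        excluded = (
            read_bed(excluded_path).get(gid, []) if excluded_path.exists() else []
        )
        numt = read_bed(numt_path).get(gid, []) if numt_path.exists() else []
        refs[gid] = ReferenceSet(
            genome_id=gid,
            sequence=seq,
            excluded_repeats=[(s, e) for s, e, *_ in excluded],
            numt_map=[(s, e, c) for s, e, c in numt],
            nuclear_genome_size=nuclear_size,
            annotation=annotation.get(gid, []),
        )
    return refs


# ---------------------------------------------------------------------------
# small TSV tables

def write_line_metadata(path: str | Path, lines) -> None:
    pd.DataFrame(
        [
            {"line_id": ln.line_id, "genotype": ln.genotype,
             "founder": ln.founder, "generations": ln.generations}
            for ln in lines
        ]
    ).to_csv(path, sep="\t", index=False)


def read_line_metadata(path: str | Path):
    from .simulate import LineMeta

    df = pd.read_csv(path, sep="\t")
    return [
        LineMeta(row.line_id, row.genotype, row.founder, int(row.generations))
        for row in df.itertuples()
    ]


def write_truth(path: str | Path, truth) -> None:
    pd.DataFrame(
        [
            {
                "line_id": m.line_id, "genome": m.genome_id, "pos": m.pos,
                "ref": m.ref, "alt": m.alt, "klass": m.klass,
                "generation_origin": m.generation_origin,
                "final_frequency": m.final_frequency,
            }
            for m in truth.mutations
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path):
    from .simulate import PlantedMutation, TruthLedger

    df = pd.read_csv(path, sep="\t")
    return TruthLedger(
        mutations=[
            PlantedMutation(
                line_id=row.line_id, genome_id=row.genome, pos=int(row.pos),
                ref=str(row.ref), alt=str(row.alt), klass=row.klass,
                generation_origin=int(row.generation_origin),
                final_frequency=float(row.final_frequency),
            )
            for row in df.itertuples()
        ]
    )


def write_read_stats(path: str | Path, stats: dict[str, dict[str, float]]) -> None:
    rows = [{"line_id": k, **v} for k, v in stats.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_read_stats(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return {row.pop("line_id"): row for row in df.to_dict("records")}


def write_homopolymer_track(path: str | Path, runs) -> None:
    pd.DataFrame(
        [{"base": r.base, "start": r.start, "length": r.length, "class": r.klass}
         for r in runs]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant output

def variants_to_frame(variants) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "line_id": v.line_id, "genome": v.genome_id, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "klass": v.klass, "depth": v.depth,
                "raw_frequency": v.raw_frequency,
                "wt_background_mean": v.wt_background_mean,
                "corrected_frequency": v.corrected_frequency,
                "zygosity": v.zygosity_label or ".",
                "context": v.context or ".",
            }
            for v in variants
        ],
        columns=[
            "line_id", "genome", "pos", "ref", "alt", "klass", "depth",
            "raw_frequency", "wt_background_mean", "corrected_frequency",
            "zygosity", "context",
        ],
    )


def write_variants_tsv(path: str | Path, variants) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path):
    """Rebuild Variant records from the TSV written by write_variants_tsv.

    Allele counts are reconstructed from depth x frequency (the table
    stores frequencies, which is what every downstream stage consumes).
    """
    from .calling import Variant

    df = pd.read_csv(path, sep="\t", dtype={"alt": str, "ref": str},
                     keep_default_na=False)
    out = []
    for row in df.itertuples():
        alt_count = int(round(row.raw_frequency * row.depth))
        v = Variant(
            line_id=row.line_id, genome_id=row.genome, pos=int(row.pos),
            ref=row.ref, alt=row.alt, klass=row.klass, depth=int(row.depth),
            alt_count=alt_count, ref_count=int(row.depth) - alt_count,
            raw_frequency=float(row.raw_frequency),
            wt_background_mean=float(row.wt_background_mean),
            corrected_frequency=float(row.corrected_frequency),
            zygosity_label=None if row.zygosity == "." else row.zygosity,
            context=None if row.context == "." else row.context,
        )
        out.append(v)
    return out


def write_variants_vcf(path: str | Path, variants) -> None:
    """Minimal VCF-like file: CHROM=genome, INFO carries the call detail."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=LINE,Number=1,Type=String,Description=\"MA line\">\n")
        fh.write("##INFO=<ID=RF,Number=1,Type=Float,Description=\"Raw frequency\">\n")
        fh.write("##INFO=<ID=CF,Number=1,Type=Float,Description=\"Corrected frequency\">\n")
        fh.write("##INFO=<ID=DP,Number=1,Type=Integer,Description=\"Depth\">\n")
        fh.write("##INFO=<ID=ZYG,Number=1,Type=String,Description=\"Zygosity label\">\n")
        fh.write("##INFO=<ID=CTX,Number=1,Type=String,Description=\"Indel context\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.genome_id, v.pos, v.line_id)):
            info = (
                f"LINE={v.line_id};RF={v.raw_frequency:.4f};"
                f"CF={v.corrected_frequency:.4f};DP={v.depth};"
                f"ZYG={v.zygosity_label or '.'};CTX={v.context or '.'}"
            )
            fh.write(
                f"{v.genome_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )
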