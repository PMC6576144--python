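"""Reading and writing the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout (VCF/GFF convention);
the BED half-open convention appears only at the I/O boundary.  Pooled
samples carry no genotype calls — per-sample allelic depths (the AD field)
are authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count", "gq"]
_NUCS = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SiteFilters:
    """Site-retention thresholds for pooled SNP tables.

    Defaults follow common pooled-resequencing practice: genotyping quality
    strictly above 30, per-sample depth between 10 and 250 inclusive, and
    SNPs within ``indel_margin`` bp of an indel discarded (boundary
    inclusive: a SNP exactly 10 bp from an indel is removed, 11 bp is kept).
    """

    min_gq: float = 30.0
    min_depth: int = 10
    max_depth: int = 250
    indel_margin: int = 10


@dataclass
class GeneModel:
    """A protein-coding gene: 1-based inclusive span plus per-transcript CDS
    intervals ``(start, end, frame)`` sorted by genomic position."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Union of CDS intervals across transcripts (deduplicated, sorted)."""
        ivs = {(s, e) for cds in self.transcripts.values() for (s, e, _f) in cds}
        return sorted(ivs)

    def cds_length(self, transcript: str | None = None) -> int:
        if transcript is None:
            transcript = next(iter(self.transcripts))
        return sum(e - s + 1 for s, e, _f in self.transcripts[transcript])


# ---------------------------------------------------------------------------
# VCF


def read_sites(vcf_path, filters: SiteFilters | None = None) -> pd.DataFrame:
    """Read one pooled sample's SNP sites from a VCF into a site table.

    Retains biallelic SNPs with genotyping quality > ``min_gq``, depth in
    [``min_depth``, ``max_depth``], and no indel within ``indel_margin`` bp.
    Drop counters are attached as ``df.attrs["filter_counts"]``.
    """
    if filters is None:
        filters = SiteFilters()
    counts = {
        "multiallelic": 0,
        "not_snp": 0,
        "low_gq": 0,
        "depth": 0,
        "near_indel": 0,
        "kept": 0,
    }
    indel_pos: dict[str, list[int]] = {}
    records = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        if len(vf.header.samples) != 1:
            raise ValueError(
                f"{vcf_path}: expected exactly one pooled sample, "
                f"found {len(vf.header.samples)}"
            )
        sample = vf.header.samples[0]
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1:
                counts["multiallelic"] += 1
                continue
            if len(alts) == 0:
                counts["not_snp"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
                # indel or symbolic allele: remember leftmost position
                indel_pos.setdefault(rec.chrom, []).append(rec.pos)
                continue
            records.append((rec.chrom, rec.pos, ref, alt, rec.samples[sample]))
    rows = []
    for chrom, pos, ref, alt, fmt in records:
        ad = fmt.get("AD")
        if ad is None or len(ad) != 2 or any(v is None for v in ad):
            raise ValueError(f"{chrom}:{pos}: missing or malformed AD field")
        gq = fmt.get("GQ")
        if gq is None:
            counts["low_gq"] += 1
            continue
        if gq <= filters.min_gq:
            counts["low_gq"] += 1
            continue
        depth = int(ad[0]) + int(ad[1])
        if not filters.min_depth <= depth <= filters.max_depth:
            counts["depth"] += 1
            continue
        near = indel_pos.get(chrom, ())
        if any(abs(pos - ip) <= filters.indel_margin for ip in near):
            counts["near_indel"] += 1
            continue
        rows.append((chrom, pos, ref, alt, int(ad[0]), int(ad[1]), float(gq)))
        counts["kept"] += 1
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.attrs["filter_counts"] = counts
    return df


def write_sites(
    table: pd.DataFrame,
    vcf_path,
    sample: str,
    contigs: dict[str, int],
) -> None:
    """Write a one-sample site table as VCF with AD carrying (ref, alt) depths."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=int(length))
    header.formats.add("GT", 1, "String", "Genotype (uncalled for pools)")
    header.formats.add("AD", "R", "Integer", "Allelic read depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("GQ", 1, "Integer", "Genotyping quality")
    header.add_sample(sample)
    table = table.sort_values(["chrom", "pos"], kind="stable")
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for row in table.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.samples[sample]["GT"] = (None, None)
            rec.samples[sample]["AD"] = (int(row.ref_count), int(row.alt_count))
            rec.samples[sample]["DP"] = int(row.ref_count + row.alt_count)
            rec.samples[sample]["GQ"] = int(row.gq)
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3


def read_genes(gff3_path) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/CDS hierarchy into GeneModels.

    A gene's span is the union across its transcripts; per-transcript CDS
    lists are kept.  CDS features outside their gene's span, or without a
    resolvable parent gene, raise ``ValueError``.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        model = GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end, strand=g.strand
        )
        for tx in db.children(g, featuretype="mRNA"):
            cds = []
            for c in db.children(tx, featuretype="CDS"):
                if c.start < g.start or c.end > g.end:
                    raise ValueError(
                        f"CDS {c.seqid}:{c.start}-{c.end} outside span of "
                        f"gene {g.id} ({g.start}-{g.end})"
                    )
                frame = int(c.frame) if c.frame not in (None, ".") else 0
                cds.append((c.start, c.end, frame))
            model.transcripts[tx.id] = sorted(cds)
        genes.append(model)
    orphans = [
        c.id
        for c in db.features_of_type("CDS")
        if not any(True for _ in db.parents(c, featuretype="mRNA"))
    ]
    if orphans:
        raise ValueError(f"orphan CDS features without mRNA parent: {orphans}")
    genes.sort(key=lambda m: (m.chrom, m.start))
    return genes


def write_genes(genes: list[GeneModel], gff3_path) -> None:
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda m: (m.chrom, m.start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tcanyonpool\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for tx_id, cds in g.transcripts.items():
                tx_start = min(s for s, _e, _f in cds)
                tx_end = max(e for _s, e, _f in cds)
                fh.write(
                    f"{g.chrom}\tcanyonpool\tmRNA\t{tx_start}\t{tx_end}\t.\t"
                    f"{g.strand}\t.\tID={tx_id};Parent={g.gene_id}\n"
                )
                for i, (s, e, frame) in enumerate(cds, 1):
                    fh.write(
                        f"{g.chrom}\tcanyonpool\tCDS\t{s}\t{e}\t.\t{g.strand}\t"
                        f"{frame}\tID={tx_id}.cds{i};Parent={tx_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED

BED_HEADER = "#chrom\tstart\tend\tname"


def write_regions(regions: pd.DataFrame, bed_path) -> None:
    """Write 1-based inclusive intervals as 4-column BED (0-based half-open).

    ``regions`` needs columns chrom/start/end and optionally ``label``.
    A 1-based inclusive interval [s, e] is emitted as (s-1, e).
    """
    regions = regions.copy()
    if "label" not in regions.columns:
        regions["label"] = "."
    bad = regions[regions["end"] < regions["start"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"interval with end < start: {r.chrom}:{r.start}-{r.end}")
    regions = regions.sort_values(["chrom", "start", "end"], kind="stable")
    with open(bed_path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for row in regions.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.label}\n")


def read_regions(bed_path) -> pd.DataFrame:
    """Read 4-column BED back into 1-based inclusive intervals."""
    rows = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start + 1, end, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


# ---------------------------------------------------------------------------
# TE calls and slope labels

TE_COLUMNS = ["family", "chrom", "pos", "line", "slope"]


def read_te_calls(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TE table missing columns {missing}")
    return df[TE_COLUMNS]


def write_te_calls(df: pd.DataFrame, tsv_path) -> None:
    df[TE_COLUMNS].to_csv(tsv_path, sep="\t", index=False)


def read_slopes(tsv_path) -> dict[str, str]:
    df = pd.read_csv(tsv_path, sep="\t")
    return dict(zip(df["line"], df["slope"]))


def write_slopes(slopes: dict[str, str], tsv_path) -> None:
    pd.DataFrame(
        {"line": list(slopes), "slope": list(slopes.values())}
    ).to_csv(tsv_path, sep="\t", index=False)


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
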