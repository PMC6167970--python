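"""RAD-locus variant processing and locus-retention cascade.

The cascade mirrors standard reduced-representation practice for datasets
without a reference genome: complex variants are decomposed to SNPs, indels
removed, contigs matching the mitochondrial genome excluded, loci with too
much missingness dropped, per-read SNP combinations collapsed to locus
haplotypes (pruning sequencing error and flagging paralogs), and finally a
joint completeness/depth rule applied.

Thresholds live in :class:`FilterConfig`; the defaults keep a locus only if it
is typed in >= 85% of individuals and confidently haplotyped at depth >= 20 in
at least 14 of 19 individuals.  The 85% rule is evaluated on the real-valued
fraction: with 19 individuals, 16/19 (0.842) fails and 17/19 (0.895) passes.

Coordinates are 1-based inclusive in VCF records (the VCF convention); any
0-based internal arithmetic is converted at I/O only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_GT = "./."

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class FilterConfig:
    """Thresholds of the locus-retention cascade."""

    min_individual_fraction: float = 0.85
    min_individuals_haplotyped: int = 14
    total_individuals: int = 19
    min_depth: int = 20
    error_fraction: float = 0.05
    kmer_size: int = 31
    min_identity: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.min_individual_fraction <= 1:
            raise ValueError("min_individual_fraction must be in (0, 1]")
        if self.min_individuals_haplotyped > self.total_individuals:
            raise ValueError("min_individuals_haplotyped must be <= total_individuals")
        if self.total_individuals < 1:
            raise ValueError("total_individuals must be >= 1")


@dataclass
class LocusRecord:
    """One variant record: contig, 1-based position, alleles, genotypes, depths."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: list[str]
    depths: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        self.depths = np.asarray(self.depths, dtype=int)
        if (self.depths < 0).any():
            raise ValueError("depths must be >= 0")

    def missing_mask(self) -> np.ndarray:
        return np.array([g == MISSING_GT for g in self.genotypes])


@dataclass
class ReadHaplotypeObservation:
    """SNP-combination string observed on reads of one individual at one contig."""

    contig: str
    individual: str
    combination: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")


@dataclass
class HaplotypeCall:
    """Collapsed haplotype genotype for one individual at one contig."""

    flag: str  # ok | paralog_suspect | low_data
    haplotypes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Variant-level operations


def _remap_genotype(gt: str, allele_map: Mapping[int, int]) -> str:
    if gt == MISSING_GT:
        return gt
    sep = "|" if "|" in gt else "/"
    return sep.join(str(allele_map[int(a)]) for a in gt.split(sep))


def decompose_complex_variants(records: Iterable[LocusRecord]) -> list[LocusRecord]:
    """Split multi-nucleotide substitutions into per-base SNP records.

    An MNP (ref and all alts the same length > 1) becomes one SNP record per
    base where any alt differs from the ref, at the correct shifted position.
    Plain SNPs and length-changing records (indels) pass through unchanged --
    indel removal is a separate step.
    """
    out: list[LocusRecord] = []
    for rec in records:
        if not rec.ref or any(not a for a in rec.alts):
            raise ValueError(f"empty allele at {rec.contig}:{rec.pos}")
        same_len = all(len(a) == len(rec.ref) for a in rec.alts)
        if len(rec.ref) == 1 or not same_len:
            out.append(rec)
            continue
        for offset in range(len(rec.ref)):
            ref_base = rec.ref[offset]
            new_alts: list[str] = []
            allele_map = {0: 0}
            for ai, alt in enumerate(rec.alts, start=1):
                base = alt[offset]
                if base == ref_base:
                    allele_map[ai] = 0
                elif base in new_alts:
                    allele_map[ai] = new_alts.index(base) + 1
                else:
                    new_alts.append(base)
                    allele_map[ai] = len(new_alts)
            if not new_alts:
                continue  # invariant column within the MNP
            out.append(
                LocusRecord(
                    contig=rec.contig,
                    pos=rec.pos + offset,
                    ref=ref_base,
                    alts=tuple(new_alts),
                    genotypes=[_remap_genotype(g, allele_map) for g in rec.genotypes],
                    depths=rec.depths,
                )
            )
    return out


def remove_indels(records: Iterable[LocusRecord]) -> list[LocusRecord]:
    """Drop any record where ref and alt allele lengths differ."""
    return [
        r for r in records if all(len(a) == len(r.ref) for a in r.alts)
    ]


def _kmer_index(seq: str, k: int) -> dict[str, int]:
    idx: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        idx.setdefault(kmer, i)
    return idx


def _anchored_identity(contig: str, reference: str, c_pos: int, r_pos: int) -> float:
    """Ungapped identity of the contig against the reference, anchored so that
    contig position c_pos aligns with reference position r_pos.  Contig bases
    falling outside the reference count as mismatches."""
    start = r_pos - c_pos
    matches = 0
    for i, base in enumerate(contig):
        j = start + i
        if 0 <= j < len(reference) and reference[j] == base:
            matches += 1
    return matches / len(contig)


def remove_mtdna_contigs(
    records: Sequence[LocusRecord],
    mtdna_sequence: str,
    contig_sequences: Mapping[str, str],
    config: FilterConfig | None = None,
) -> tuple[list[LocusRecord], list[str]]:
    """Remove contigs that match the mitochondrial reference.

    A contig is removed iff it shares an exact k-mer seed with the mtDNA (either
    strand) and the seed-anchored ungapped identity over the whole contig is at
    least ``min_identity``.  Contigs without a sequence are retained.
    Returns (nuclear-only records, removed contig ids).
    """
    config = config or FilterConfig()
    mt = mtdna_sequence.upper()
    if not mt:
        raise ValueError("empty mtDNA reference")
    k = config.kmer_size
    fwd = _kmer_index(mt, k)
    rev = _kmer_index(mt.translate(_COMPLEMENT)[::-1], k)

    removed: list[str] = []
    for contig in sorted({r.contig for r in records}):
        seq = contig_sequences.get(contig, "").upper()
        if len(seq) < k:
            continue
        hit = False
        for ref_seq, index in ((mt, fwd), (mt.translate(_COMPLEMENT)[::-1], rev)):
            for i in range(len(seq) - k + 1):
                j = index.get(seq[i : i + k])
                if j is None:
                    continue
                if _anchored_identity(seq, ref_seq, i, j) >= config.min_identity:
                    hit = True
                break  # one seed per strand decides; chains start at first shared k-mer
            if hit:
                break
        if hit:
            removed.append(contig)
    removed_set = set(removed)
    return [r for r in records if r.contig not in removed_set], removed


# ---------------------------------------------------------------------------
# Locus-level filters


def _typed_individuals(records: Sequence[LocusRecord]) -> np.ndarray:
    """Individuals with a non-missing genotype at every record of a contig."""
    mask = ~records[0].missing_mask()
    for rec in records[1:]:
        mask &= ~rec.missing_mask()
    return mask


def group_by_contig(records: Iterable[LocusRecord]) -> dict[str, list[LocusRecord]]:
    grouped: dict[str, list[LocusRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.contig, []).append(rec)
    return grouped


def filter_locus_missingness(
    records: Iterable[LocusRecord], config: FilterConfig
) -> list[LocusRecord]:
    """Keep a locus iff typed in >= ``min_individual_fraction`` of individuals.

    The comparison is on the real-valued fraction, so with 19 individuals the
    85% rule requires at least 17 typed (16/19 = 0.842 fails).
    """
    if config.total_individuals == 0:
        raise ValueError("total_individuals must be positive")
    out: list[LocusRecord] = []
    for contig, recs in group_by_contig(records).items():
        typed = int(_typed_individuals(recs).sum())
        if typed / config.total_individuals >= config.min_individual_fraction:
            out.extend(recs)
    return out


def collapse_reads_to_haplotypes(
    observations: "pd.DataFrame | Iterable[ReadHaplotypeObservation]",
    records: Sequence[LocusRecord],
    error_fraction: float = 0.05,
) -> dict[str, dict[str, HaplotypeCall]]:
    """Collapse per-read SNP combinations into per-individual locus haplotypes.

    At each (contig, individual), combinations supported by fewer than
    ``error_fraction`` of that individual's reads at the contig are pruned as
    sequencing error.  Individuals with more than two surviving combinations
    are flagged ``paralog_suspect``, with none ``low_data``, otherwise ``ok``
    with the 1-2 surviving haplotypes as the genotype.
    """
    if isinstance(observations, pd.DataFrame):
        obs_iter = [
            ReadHaplotypeObservation(r.contig, r.individual, r.combination, int(r.count))
            for r in observations.itertuples(index=False)
        ]
    else:
        obs_iter = list(observations)

    known_contigs = {r.contig for r in records}
    n_sites = {c: len(recs) for c, recs in group_by_contig(records).items()}
    grouped: dict[tuple[str, str], dict[str, int]] = {}
    for o in obs_iter:
        if o.contig not in known_contigs:
            raise ValueError(f"observation references unknown contig {o.contig!r}")
        if len(o.combination) != n_sites[o.contig]:
            raise ValueError(
                f"{o.contig}/{o.individual}: combination length {len(o.combination)} "
                f"!= {n_sites[o.contig]} variant sites"
            )
        key = (o.contig, o.individual)
        grouped.setdefault(key, {})
        grouped[key][o.combination] = grouped[key].get(o.combination, 0) + o.count

    calls: dict[str, dict[str, HaplotypeCall]] = {}
    for (contig, ind), combos in sorted(grouped.items()):
        total = sum(combos.values())
        surviving = sorted(
            c for c, n in combos.items() if n / total >= error_fraction
        )
        if not surviving:
            call = HaplotypeCall(flag="low_data")
        elif len(surviving) > 2:
            call = HaplotypeCall(flag="paralog_suspect", haplotypes=tuple(surviving))
        else:
            call = HaplotypeCall(flag="ok", haplotypes=tuple(surviving))
        calls.setdefault(contig, {})[ind] = call
    return calls


def filter_haplotyped_loci(
    calls: Mapping[str, Mapping[str, HaplotypeCall]],
    depths: "pd.DataFrame | Mapping[str, Mapping[str, int]]",
    config: FilterConfig,
) -> list[str]:
    """Keep a locus iff cleanly haplotyped at sufficient depth in enough individuals.

    An individual qualifies when its call flag is ``ok`` AND its read depth at
    the contig is >= ``min_depth``; the locus is kept when at least
    ``min_individuals_haplotyped`` individuals qualify (boundary inclusive).
    """
    def depth_of(contig: str, ind: str) -> int:
        if isinstance(depths, pd.DataFrame):
            return int(depths.loc[contig, ind])
        return int(depths[contig][ind])

    kept = []
    for contig in sorted(calls):
        qualifying = sum(
            1
            for ind, call in calls[contig].items()
            if call.flag == "ok" and depth_of(contig, ind) >= config.min_depth
        )
        if qualifying >= config.min_individuals_haplotyped:
            kept.append(contig)
    return kept


# ---------------------------------------------------------------------------
# Genotype matrix and VCF I/O


@dataclass
class GenotypeMatrix:
    """Loci x individuals biallelic genotypes with per-cell depth."""

    genotypes: pd.DataFrame  # index (contig, pos), columns individuals
    depths: pd.DataFrame
    ref: pd.Series
    alts: pd.Series


def export_genotype_matrix(
    records: Sequence[LocusRecord],
    individuals: Sequence[str],
    path: "str | Path | None" = None,
) -> GenotypeMatrix:
    """Build the final genotype matrix, optionally writing a VCF alongside."""
    index = pd.MultiIndex.from_tuples(
        [(r.contig, r.pos) for r in records], names=["contig", "pos"]
    )
    gm = GenotypeMatrix(
        genotypes=pd.DataFrame(
            [r.genotypes for r in records], index=index, columns=list(individuals)
        ),
        depths=pd.DataFrame(
            [r.depths for r in records], index=index, columns=list(individuals)
        ),
        ref=pd.Series([r.ref for r in records], index=index),
        alts=pd.Series([",".join(r.alts) or "." for r in records], index=index),
    )
    if path is not None:
        write_vcf(records, individuals, path)
    return gm


def _format_ad(gt: str, n_alleles: int, depth: int) -> str:
    """Synthesize an AD field consistent with GT and DP (even split for hets)."""
    ad = [0] * n_alleles
    if gt != MISSING_GT and depth > 0:
        alleles = [int(a) for a in gt.replace("|", "/").split("/")]
        if alleles[0] == alleles[1]:
            ad[alleles[0]] = depth
        else:
            ad[alleles[0]] = depth // 2
            ad[alleles[1]] = depth - depth // 2
    return ",".join(str(x) for x in ad)


def write_vcf(
    records: Sequence[LocusRecord], individuals: Sequence[str], path: "str | Path"
) -> None:
    """Write records as VCF 4.2 with GT:DP:AD, deterministically ordered."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=gilakit",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for contig in sorted({r.contig for r in records}):
        lines.append(f"##contig=<ID={contig}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(individuals)
    )
    for rec in sorted(records, key=lambda r: (r.contig, r.pos)):
        alt = ",".join(rec.alts) if rec.alts else "."
        n_alleles = 1 + len(rec.alts)
        samples = []
        for gt, dp in zip(rec.genotypes, rec.depths):
            dp_field = "." if gt == MISSING_GT else str(int(dp))
            ad = "." if gt == MISSING_GT else _format_ad(gt, n_alleles, int(dp))
            samples.append(f"{gt}:{dp_field}:{ad}")
        lines.append(
            f"{rec.contig}\t{rec.pos}\t.\t{rec.ref}\t{alt}\t.\tPASS\t.\tGT:DP:AD\t"
            + "\t".join(samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: "str | Path") -> tuple[list[LocusRecord], list[str]]:
    """Read a VCF (GT + DP) back into records. Uses cyvcf2 when available."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - fallback parser
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    records = []
    for v in vcf:
        gts = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            gts.append(MISSING_GT if a < 0 or b < 0 else f"{min(a,b)}/{max(a,b)}")
        depths = v.format("DP")
        depths = (
            np.nan_to_num(depths.astype(float), nan=0).astype(int).reshape(-1)
            if depths is not None
            else np.zeros(len(individuals), dtype=int)
        )
        depths = np.where(depths < 0, 0, depths)
        records.append(
            LocusRecord(
                contig=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=gts,
                depths=depths,
            )
        )
    return records, individuals


def _read_vcf_text(path: "str | Path") -> tuple[list[LocusRecord], list[str]]:
    records: list[LocusRecord] = []
    individuals: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line:
            continue
        fields = line.split("\t")
        if line.startswith("#CHROM"):
            individuals = fields[9:]
            continue
        fmt = fields[8].split(":")
        gt_i, dp_i = fmt.index("GT"), fmt.index("DP")
        gts, dps = [], []
        for cell in fields[9:]:
            parts = cell.split(":")
            gt = parts[gt_i].replace("|", "/")
            gts.append(MISSING_GT if "." in gt else gt)
            dps.append(0 if parts[dp_i] == "." else int(parts[dp_i]))
        records.append(
            LocusRecord(
                contig=fields[0],
                pos=int(fields[1]),
                ref=fields[3],
                alts=tuple(a for a in fields[4].split(",") if a != "."),
                genotypes=gts,
                depths=np.array(dps),
            )
        )
    return records, individuals


def run_cascade(
    records: Sequence[LocusRecord],
    config: FilterConfig,
    mtdna_sequence: str | None = None,
    contig_sequences: Mapping[str, str] | None = None,
    observations: "pd.DataFrame | None" = None,
    depths: "pd.DataFrame | None" = None,
) -> dict:
    """Run the full retention cascade; returns records, kept loci and a log.

    Order: decompose -> indel removal -> mtDNA removal (if a reference is
    given) -> missingness filter -> haplotype collapse + depth/completeness
    rule (if read observations are given).
    """
    log: dict[str, object] = {"input_records": len(records)}
    recs = decompose_complex_variants(records)
    log["after_decompose"] = len(recs)
    recs = remove_indels(recs)
    log["after_indel_removal"] = len(recs)
    removed_mt: list[str] = []
    if mtdna_sequence is not None:
        recs, removed_mt = remove_mtdna_contigs(
            recs, mtdna_sequence, contig_sequences or {}, config
        )
    log["mtdna_contigs_removed"] = len(removed_mt)
    recs = filter_locus_missingness(recs, config)
    log["after_missingness"] = len(recs)
    kept_contigs = sorted({r.contig for r in recs})
    if observations is not None and depths is not None:
        contig_set = set(kept_contigs)
        obs = observations[observations["contig"].isin(contig_set)]
        calls = collapse_reads_to_haplotypes(obs, recs, config.error_fraction)
        kept_contigs = filter_haplotyped_loci(calls, depths, config)
        recs = [r for r in recs if r.contig in set(kept_contigs)]
    log["final_loci"] = len(kept_contigs)
    log["final_records"] = len(recs)
    return {"records": recs, "kept_loci": kept_contigs, "log": log}
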