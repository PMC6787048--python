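"""Readers/writers for the pipeline's on-disk formats.

FASTA via Bio.SeqIO, VCF via pysam; BED/bedGraph/TSV are written with
pandas or plain formatting.  All genomic intervals are 0-based half-open
except in VCF (1-based) and the observation TSV (1-based positions, as
variant callers emit them).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binmap import BinMapResult
from .probes import DensityTrack, OligoPair, ProbeSet
from .screen import KmerIndex, Oligo
from .synthetic import HaplotypePair, VariantTruth
from .thermo import DEFAULT_CONDITIONS, melting_temperature


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_oligos_fasta(oligos: Iterable[Oligo], path: str | os.PathLike) -> None:
    """Oligos as FASTA with ``chrom:start-end`` ids."""
    records = [SeqRecord(Seq(o.seq), id=o.name, description="") for o in oligos]
    SeqIO.write(records, str(path), "fasta")


def write_oligos_bed(oligos: Iterable[Oligo], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for o in oligos:
            fh.write(f"{o.chrom}\t{o.start}\t{o.end}\t{o.name}\t0\t{o.strand}\n")


def write_oligo_tsv(oligos: Sequence[Oligo], index: KmerIndex,
                    path: str | os.PathLike, freq_threshold: int = 100) -> None:
    """Retained oligos with their repetitive k-mer counts."""
    from .screen import count_repetitive_kmers

    rows = [
        {"id": o.name, "chrom": o.chrom, "start": o.start, "end": o.end,
         "n_repetitive_kmers": count_repetitive_kmers(o, index, freq_threshold)}
        for o in oligos
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pairs_tsv(pairs: Sequence[OligoPair], path: str | os.PathLike,
                    cond=DEFAULT_CONDITIONS) -> None:
    rows = []
    for p in pairs:
        rows.append({
            "id": p.member_a.name,
            "class": p.snp_class,
            "n_variants": p.n_variants,
            "tm_a": round(melting_temperature(p.member_a.seq, cond), 3),
            "tm_b": round(melting_temperature(p.member_b.seq, cond), 3),
            "delta_tm": round(p.delta_tm, 3),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_probe_set(pset: ProbeSet, prefix: str) -> None:
    """FASTA + BED + composition TSV under ``prefix``."""
    write_oligos_fasta(pset.members, f"{prefix}.fasta")
    write_oligos_bed(pset.members, f"{prefix}.bed")
    comp = pd.DataFrame(
        [{"class": k, "count": v} for k, v in pset.composition.items()]
        + [{"class": "total", "count": pset.size}]
    )
    comp.to_csv(f"{prefix}.composition.tsv", sep="\t", index=False)


def write_bedgraph(track: DensityTrack, chrom: str, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(track.counts.tolist()):
            lo = i * track.window_bp
            hi = min(lo + track.window_bp, track.chrom_len)
            fh.write(f"{chrom}\t{lo}\t{hi}\t{c}\n")


def write_truth_tsv(truth: Sequence[VariantTruth], path: str | os.PathLike) -> None:
    """Variant truth with 0-based positions."""
    pd.DataFrame(
        [{"position": v.position, "vtype": v.vtype, "ref_allele": v.ref_allele,
          "alt_allele": v.alt_allele} for v in truth]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | os.PathLike) -> list[VariantTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        VariantTruth(int(r.position), str(r.vtype), str(r.ref_allele), str(r.alt_allele))
        for r in df.itertuples()
    ]


def write_truth_vcf(pair: HaplotypePair, path: str | os.PathLike,
                    chrom: str = "chr1") -> None:
    """Variant truth as VCF (1-based; haplotype A is the reference)."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={len(pair.seq_a)}>")
    header.add_line('##INFO=<ID=VT,Number=1,Type=String,Description="Variant truth class">')
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in pair.truth:
            p = v.position
            if v.vtype == "snp":
                start, ref, alt = p, v.ref_allele, v.alt_allele
            elif v.vtype in ("deletion", "pav_deletion"):
                if p == 0:
                    raise ValueError("deletion at position 0 cannot be anchored in VCF")
                start = p - 1
                ref = pair.seq_a[p - 1 : p + len(v.ref_allele)]
                alt = pair.seq_a[p - 1]
            else:  # insertion / pav_insertion
                if p == 0:
                    raise ValueError("insertion at position 0 cannot be anchored in VCF")
                start = p - 1
                ref = pair.seq_a[p - 1]
                alt = ref + v.alt_allele
            rec = vcf.new_record(contig=chrom, start=start, alleles=(ref, alt))
            rec.info["VT"] = v.vtype
            vcf.write(rec)


def write_observations_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_observations_vcf(path: str | os.PathLike, sample: str | None = None) -> pd.DataFrame:
    """Biallelic parental calls from a VCF: genotype 0/0 -> P1 (reference
    haplotype allele), 1/1 or 0/1 with alt support -> P2.  QUAL, INFO/DP and
    INFO/MQ populate the filter columns (DP/MQ fall back to FORMAT fields)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = sample or (next(iter(vcf.header.samples)) if list(vcf.header.samples) else None)
        for rec in vcf:
            if len(rec.alleles or ()) != 2:
                continue
            if sample is not None:
                gt = rec.samples[sample].get("GT", (None,))
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    continue
                allele = "P2" if any(a == 1 for a in alleles) else "P1"
                depth = rec.samples[sample].get("DP") or rec.info.get("DP", 1)
            else:
                allele = "P2"
                depth = rec.info.get("DP", 1)
            mq = rec.info.get("MQ", 60)
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos, "allele": allele,
                "depth": int(depth or 1), "qual": float(rec.qual or 0.0),
                "mapq": float(mq if mq is not None else 60),
            })
    return pd.DataFrame(rows)


def write_binmap_result(result: BinMapResult, prefix: str, chrom: str = "chr1") -> None:
    """Bin map TSV + segments BED + exchange-point TSV."""
    pd.DataFrame(
        [{"window": i, "first_snp_index": w.first_snp_index, "n_snps": w.n_snps,
          "start_bp": w.span_bp[0], "end_bp": w.span_bp[1],
          "frac_p1": round(w.frac_p1, 4), "call": w.call}
         for i, w in enumerate(result.windows)]
    ).to_csv(f"{prefix}.windows.tsv", sep="\t", index=False)
    with open(f"{prefix}.segments.bed", "w") as fh:
        for s in result.segments:
            flag = "low_confidence" if s.low_confidence else "."
            fh.write(f"{chrom}\t{s.bp_range[0] - 1}\t{s.bp_range[1]}\t{s.call}\t0\t+\t{flag}\n")
    pd.DataFrame(
        [{"left_bound_bp": e.left_bound_bp, "right_bound_bp": e.right_bound_bp,
          "mid_bp": e.mid_bp, "transition": "->".join(e.transition),
          "low_confidence": e.low_confidence,
          "ambiguous_double_co": e.ambiguous_double_co}
         for e in result.exchange_points]
    ).to_csv(f"{prefix}.exchange_points.tsv", sep="\t", index=False)
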