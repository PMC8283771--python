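"""Build transcripts from a genome FASTA plus GTF/GFF3 annotation.

One transcript is chosen per gene: the annotated isoform with the most
exons, ties broken lexicographically by transcript identifier.  Annotation
coordinates follow the GTF convention (1-based, inclusive); minus-strand
transcripts are reverse-complemented so exons and introns read 5'->3' in
transcript orientation.
"""

from __future__ import annotations

import gffutils
from pyfaidx import Fasta

from .dataset import Transcript

__all__ = ["load_transcripts"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def load_transcripts(fasta_path: str, gtf_path: str) -> list[Transcript]:
    """Read one maximum-exon transcript per gene from a genome + annotation.

    Returns transcripts in gene-id order.  Raises on overlapping or
    unsorted exon intervals within a transcript.
    """
    db = gffutils.create_db(
        gtf_path, ":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genome = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)

    by_gene: dict[str, list] = {}
    for tx in db.features_of_type(("transcript", "mRNA")):
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        by_gene.setdefault(gene_id, []).append(tx)

    transcripts = []
    for gene_id in sorted(by_gene):
        candidates = []
        for tx in by_gene[gene_id]:
            exons = sorted(db.children(tx, featuretype="exon"),
                           key=lambda e: e.start)
            candidates.append((len(exons), tx.id, tx, exons))
        # most exons first; ties broken lexicographically by transcript id
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, tx_id, tx, exons = candidates[0]
        if len(exons) < 2:
            continue
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{tx_id}: exon intervals overlap or are unsorted "
                    f"({a.start}-{a.end} vs {b.start}-{b.end})"
                )
        exon_seqs = [str(genome[e.seqid][e.start - 1:e.end]) for e in exons]
        intron_seqs = [str(genome[a.seqid][a.end:b.start - 1])
                       for a, b in zip(exons, exons[1:])]
        if tx.strand == "-":
            exon_seqs = [_revcomp(s) for s in reversed(exon_seqs)]
            intron_seqs = [_revcomp(s) for s in reversed(intron_seqs)]
        transcripts.append(Transcript(
            gene_id=gene_id, transcript_id=tx_id,
            exons=exon_seqs, introns=intron_seqs,
        ))
    return transcripts
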