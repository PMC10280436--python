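"""Synthetic genome + transcript-annotation fixtures with a planted TSS motif.

Real TSS datasets are built from a reference genome and an Ensembl transcript
annotation. This module emulates that input at arbitrary (small) scale: random
background chromosomes, planted transcripts, and a noisy consensus motif
written at each transcription start site, so that every downstream stage —
window extraction, negative sampling, kernels, classifiers — has a learnable
signal to find without any external download.

The fixture deliberately omits real-genome structure (exons, CpG islands,
isoform TSS clusters, soft masking, N runs); it provides exactly the geometry
and signal the pipeline contracts need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError

BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Columns of a transcript annotation table, in canonical order.
ANNOTATION_COLUMNS = [
    "transcript_id",
    "chromosome",
    "strand",
    "transcript_start",
    "transcript_end",
    "tss",
]


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T} (case preserved upper)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Parameters of the synthetic genome generator.

    ``upstream_margin``/``downstream_margin`` guarantee that every planted TSS
    admits a full extraction window on either strand; the defaults (700 / 303)
    cover the standard 700-base upstream flank and the 3-base TSS codon plus
    300-base downstream flank.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    n_transcripts: int = 20
    motif: str = "TATAAA"
    motif_noise: float = 0.1
    background_gc: float = 0.41
    seed: int = 0
    upstream_margin: int = 700
    downstream_margin: int = 303
    min_transcript_halfspan: int = 50
    max_transcript_halfspan: int = 1_500

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be a positive integer")
        if self.n_transcripts < 1:
            raise ConfigurationError("n_transcripts must be a positive integer")
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ConfigurationError("motif must be a non-empty string over A,C,G,T")
        if not 0.0 <= self.motif_noise <= 1.0:
            raise ConfigurationError("motif_noise must lie in [0, 1]")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ConfigurationError("background_gc must lie in [0, 1]")
        min_len = self.upstream_margin + self.downstream_margin + len(self.motif) + 1
        if self.chromosome_length < min_len:
            raise ConfigurationError(
                "chromosome_length must be at least upstream_margin + "
                f"downstream_margin + motif length + 1 = {min_len}"
            )
        if self.chromosome_length < 2 * self._margin() + 2:
            raise ConfigurationError(
                "chromosome_length too short to place a TSS with full flanks "
                f"(need > {2 * self._margin() + 1} bases)"
            )

    def _margin(self) -> int:
        # symmetric safety margin valid for both strands
        return max(self.upstream_margin, self.downstream_margin + len(self.motif))


def generate_fixture(
    config: SyntheticGenomeConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a (genome assembly, transcript annotation) pair.

    Returns
    -------
    assembly : dict mapping chromosome name -> uppercase ACGT sequence
    annotation : DataFrame with columns ``ANNOTATION_COLUMNS``; 1-based
        inclusive coordinates, one row per transcript.

    Deterministic given ``config.seed``. The motif is written on the
    transcript's strand starting at the TSS (reverse-complemented into the
    reference for minus-strand transcripts) with per-base corruption
    probability ``motif_noise`` (a corrupted base is redrawn uniformly from
    all four bases, so each motif base is retained with probability
    1 - noise + noise/4).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    p_gc = config.background_gc / 2.0
    p_at = (1.0 - config.background_gc) / 2.0
    base_probs = np.array([p_at, p_gc, p_gc, p_at])

    chrom_names = [str(i + 1) for i in range(config.n_chromosomes)]
    chroms: dict[str, np.ndarray] = {
        name: rng.choice(4, size=config.chromosome_length, p=base_probs)
        for name in chrom_names
    }

    # Balanced strands, shuffled deterministically.
    n = config.n_transcripts
    strands = np.array(["+"] * ((n + 1) // 2) + ["-"] * (n // 2))
    rng.shuffle(strands)
    chrom_of = rng.choice(config.n_chromosomes, size=n)

    motif_codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in config.motif])
    margin = config._margin()
    L = config.chromosome_length
    records = []
    for i in range(n):
        name = chrom_names[chrom_of[i]]
        strand = strands[i]
        tss = int(rng.integers(margin + 1, L - margin + 1))  # 1-based

        # Plant the (noisy) motif on the transcript strand.
        corrupted = motif_codes.copy()
        noise_mask = rng.random(len(corrupted)) < config.motif_noise
        corrupted[noise_mask] = rng.integers(0, 4, size=int(noise_mask.sum()))
        seq = chroms[name]
        if strand == "+":
            seq[tss - 1 : tss - 1 + len(corrupted)] = corrupted
        else:
            # transcript 5'->3' runs toward lower coordinates; revcomp = 3 - code
            seq[tss - len(corrupted) : tss] = (3 - corrupted)[::-1]

        h1 = int(rng.integers(config.min_transcript_halfspan, config.max_transcript_halfspan + 1))
        h2 = int(rng.integers(config.min_transcript_halfspan, config.max_transcript_halfspan + 1))
        start = max(margin + 1, tss - h1)
        end = min(L - margin, tss + h2)
        records.append((f"TX{i:05d}", name, strand, start, end, tss))

    assembly = {name: "".join(BASES[codes]) for name, codes in chroms.items()}
    annotation = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    return assembly, annotation


def write_fixture(
    assembly: dict[str, str],
    annotation: pd.DataFrame,
    genome_path,
    annotation_path,
) -> None:
    """Write the assembly as multi-record FASTA and the annotation as TSV.

    The TSV header matches the column map expected by
    :func:`tsskit.dataset.read_biomart_export` with its default mapping.
    """
    fasta_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in assembly.items()
    ]
    SeqIO.write(fasta_records, genome_path, "fasta")
    annotation.to_csv(annotation_path, sep="\t", index=False)


def read_genome_fasta(path) -> dict[str, str]:
    """Read a FASTA genome into a chromosome-name -> uppercase-sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
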