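"""Desk-scale study definitions: the strong planted-motif learnability
fixture and its cross-species counterparts.

Full-genome TSS benchmarks need hours of training; these fixtures are the
package's property-scale stand-in. The conditions are fixed here once so
tests, examples and the acceptance script all run the same study:

* a 16-base consensus motif planted at every TSS with 5% per-base noise — a
  near-deterministic signal, which is what "strong" means here;
* a 20-base window (4 upstream + 3-base TSS codon + 13 downstream) so the
  motif spans most of the window and a final-state recurrent model can read
  it at desk scale;
* five chromosomes, 100 transcripts, 10 negatives per positive (~660 train
  instances at 1:10 once chromosome 4 is held out for validation and
  chromosome 5 for test).

Cross-species generalization is emulated by regenerating the genome with a
different seed: the "same species" counterpart keeps the motif (shared
signal), the "different species" null replaces it with an unrelated random
motif, so a model transferred without retraining should score well on the
former and near chance on the latter.
"""

from __future__ import annotations

import numpy as np

from .dataset import (
    DatasetSplit,
    WindowParams,
    build_dataset,
    split_by_chromosome,
)
from .synthetic import SyntheticGenomeConfig, generate_fixture

STRONG_MOTIF = "TATAAAGGCCGATCGC"
LEARNABILITY_WINDOW = WindowParams(upstream_flank=4, codon_length=3, downstream_flank=13)
VALIDATION_CHROMOSOMES = frozenset({"4"})
TEST_CHROMOSOMES = frozenset({"5"})


def learnability_genome_config(seed: int, motif: str = STRONG_MOTIF) -> SyntheticGenomeConfig:
    """Genome generator settings for the desk-scale learnability study."""
    return SyntheticGenomeConfig(
        n_chromosomes=5,
        chromosome_length=20_000,
        n_transcripts=100,
        motif=motif,
        motif_noise=0.05,
        background_gc=0.5,  # uniform composition: the motif pattern is the only signal
        seed=seed,
        upstream_margin=25,
        downstream_margin=25,
    )


def build_learnability_split(seed: int, motif: str = STRONG_MOTIF) -> DatasetSplit:
    """Generate the fixture genome and return its chromosome-holdout split."""
    assembly, annotation = generate_fixture(learnability_genome_config(seed, motif))
    dataset = build_dataset(
        assembly, annotation, LEARNABILITY_WINDOW, n_negatives_per_positive=10, seed=seed + 1
    )
    return split_by_chromosome(dataset, VALIDATION_CHROMOSOMES, TEST_CHROMOSOMES)


def unrelated_motif(seed: int, motif: str = STRONG_MOTIF) -> str:
    """An independent uniformly random motif of the same length.

    Positions agree with the reference only at the chance rate (1/4 each), so
    the null species' planted signal is unrelated to the learned one without
    being systematically anti-matched (forcing all positions to differ would
    itself be a signal a motif detector anti-fires on).
    """
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=len(motif)))


def build_null_species_split(seed: int) -> DatasetSplit:
    """A species with a different random motif at every TSS: motif corruption
    probability 1 randomizes each planted site independently, so the genome
    shares no signal with the learned one. A single fixed alternative motif
    would not do: whatever its chance resemblance to the learned motif, it
    shifts every positive's score by the same amount and the measured AUC
    lands far from 1/2 in either direction; per-site randomization is the
    null whose transferred-model AUC is centred at 1/2."""
    config = learnability_genome_config(seed)
    config = SyntheticGenomeConfig(
        **{**config.__dict__, "motif_noise": 1.0}
    )
    assembly, annotation = generate_fixture(config)
    dataset = build_dataset(
        assembly, annotation, LEARNABILITY_WINDOW, n_negatives_per_positive=10, seed=seed + 1
    )
    return split_by_chromosome(dataset, VALIDATION_CHROMOSOMES, TEST_CHROMOSOMES)
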