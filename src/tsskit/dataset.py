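"""Labeled TSS window datasets: extraction, negative sampling, splits, I/O.

The pipeline mirrors the standard construction for TSS classifiers built from
an Ensembl-style annotation: for each transcript the TSS base and the two
following bases are treated as a codon; 700 bases before this codon and 300
after it are concatenated into a 1,003-nucleotide window (positive instance).
Negative instances are semi-synthetic: random positions inside the transcript
that are not an annotated TSS, windowed identically, at a default ratio of 10
negatives per positive. Train/validation/test partitions are assigned by
whole chromosomes (default: chromosome 16 validation; 1, 3, 13, 19, 21 test)
to prevent positional leakage.

All coordinates are 1-based inclusive (Ensembl convention). Windows are
reported 5'->3' on the transcript's strand; minus-strand spans are
reverse-complemented.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousBaseError,
    BoundaryError,
    ChromosomeLookupError,
    ConfigurationError,
    ContractError,
    DatasetParseError,
    SchemaError,
)
from .synthetic import ANNOTATION_COLUMNS, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_VALIDATION_CHROMOSOMES = frozenset({"16"})
DEFAULT_TEST_CHROMOSOMES = frozenset({"1", "3", "13", "19", "21"})

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class WindowParams:
    """Geometry of an extraction window around the TSS codon.

    Defaults give the standard 700 + 3 + 300 = 1,003-base window.
    """

    upstream_flank: int = 700
    codon_length: int = 3
    downstream_flank: int = 300

    @property
    def length(self) -> int:
        return self.upstream_flank + self.codon_length + self.downstream_flank

    def validate(self) -> None:
        if self.upstream_flank < 0 or self.downstream_flank < 0 or self.codon_length < 1:
            raise ConfigurationError("window flanks must be >= 0 and codon_length >= 1")


@dataclass(frozen=True)
class WindowInstance:
    """One labeled window with provenance."""

    sequence: str
    label: int  # 1 positive, 0 negative
    chromosome: str
    anchor: int  # 1-based coordinate of the anchor base (the TSS for positives)
    strand: str
    transcript_id: str


@dataclass
class LabeledDataset:
    """An ordered collection of window instances plus build provenance."""

    instances: list[WindowInstance]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def n_positive(self) -> int:
        return sum(inst.label == 1 for inst in self.instances)

    @property
    def n_negative(self) -> int:
        return sum(inst.label == 0 for inst in self.instances)

    @property
    def negative_ratio(self) -> float:
        n_pos = self.n_positive
        return self.n_negative / n_pos if n_pos else float("nan")

    def sequences(self) -> list[str]:
        return [inst.sequence for inst in self.instances]

    def labels(self) -> np.ndarray:
        return np.array([inst.label for inst in self.instances], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [i.sequence for i in self.instances],
                "label": [i.label for i in self.instances],
                "chromosome": [i.chromosome for i in self.instances],
                "anchor": [i.anchor for i in self.instances],
                "strand": [i.strand for i in self.instances],
                "transcript_id": [i.transcript_id for i in self.instances],
            }
        )


@dataclass
class DatasetSplit:
    """Chromosome-holdout partition into train / validation / test."""

    train: LabeledDataset
    validation: LabeledDataset
    test: LabeledDataset
    validation_chromosomes: frozenset
    test_chromosomes: frozenset


def extract_window(
    assembly: dict[str, str],
    chromosome: str,
    tss: int,
    strand: str,
    params: WindowParams = WindowParams(),
) -> str:
    """Extract the window anchored at a (1-based) TSS coordinate.

    Read 5'->3' on the transcript strand, the TSS codon occupies window
    positions ``upstream_flank + 1 .. upstream_flank + codon_length``.
    Minus-strand windows are the reverse complement of the corresponding
    reference span.
    """
    params.validate()
    if chromosome not in assembly:
        raise ChromosomeLookupError(f"unknown chromosome {chromosome!r}")
    if strand not in ("+", "-"):
        raise ContractError(f"strand must be '+' or '-', got {strand!r}")
    seq = assembly[chromosome]
    if strand == "+":
        start = tss - params.upstream_flank
        end = tss + params.codon_length - 1 + params.downstream_flank
    else:
        start = tss - params.codon_length + 1 - params.downstream_flank
        end = tss + params.upstream_flank
    if start < 1 or end > len(seq):
        raise BoundaryError(
            f"window [{start}, {end}] at tss={tss} ({strand}) exceeds chromosome "
            f"{chromosome!r} of length {len(seq)}"
        )
    window = seq[start - 1 : end]
    if strand == "-":
        window = reverse_complement(window)
    bad = set(window) - _VALID_BASES
    if bad:
        raise AmbiguousBaseError(
            f"window at {chromosome}:{tss} ({strand}) contains non-ACGT "
            f"characters {sorted(bad)}"
        )
    return window


def _window_fits(chrom_len: int, pos: int, strand: str, params: WindowParams) -> bool:
    if strand == "+":
        return pos - params.upstream_flank >= 1 and (
            pos + params.codon_length - 1 + params.downstream_flank <= chrom_len
        )
    return (
        pos - params.codon_length + 1 - params.downstream_flank >= 1
        and pos + params.upstream_flank <= chrom_len
    )


def sample_negative_anchors(
    record,
    all_tss_on_chromosome: set[int],
    n: int,
    params: WindowParams,
    assembly: dict[str, str],
    rng,
    exclusion_radius: int = 0,
) -> list[int]:
    """Sample anchor coordinates for negatives inside one transcript's span.

    Coordinates are drawn uniformly without replacement from positions within
    ``[transcript_start, transcript_end]`` that are not within
    ``exclusion_radius`` of any annotated TSS and that admit a full window on
    the transcript's strand. When fewer than ``n`` positions are eligible,
    all of them are returned and a warning is logged.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    chrom_len = len(assembly[record.chromosome])
    positions = np.arange(record.transcript_start, record.transcript_end + 1)
    tss_arr = np.fromiter(all_tss_on_chromosome, dtype=int) if all_tss_on_chromosome else np.empty(0, int)
    if len(tss_arr):
        near_tss = np.abs(positions[:, None] - tss_arr[None, :]).min(axis=1) <= exclusion_radius
    else:
        near_tss = np.zeros(len(positions), bool)
    fits = np.array([_window_fits(chrom_len, int(p), record.strand, params) for p in positions])
    eligible = positions[~near_tss & fits]
    if len(eligible) == 0:
        logger.warning(
            "transcript %s has no eligible negative positions", record.transcript_id
        )
        return []
    if len(eligible) < n:
        logger.warning(
            "transcript %s has only %d eligible negative positions (requested %d)",
            record.transcript_id,
            len(eligible),
            n,
        )
        return [int(p) for p in eligible]
    return [int(p) for p in rng.choice(eligible, size=n, replace=False)]


def build_dataset(
    assembly: dict[str, str],
    annotation: pd.DataFrame,
    params: WindowParams = WindowParams(),
    n_negatives_per_positive: int = 10,
    seed: int = 0,
    exclusion_radius: int = 0,
    dedup_positives: bool = False,
) -> LabeledDataset:
    """Build a labeled dataset: one positive per transcript plus sampled negatives.

    Windows containing non-ACGT characters or falling outside their chromosome
    are discarded and counted in the provenance. Deterministic given ``seed``.
    """
    if annotation is None or len(annotation) == 0:
        raise ConfigurationError("annotation must be non-empty")
    params.validate()
    rng = np.random.default_rng(seed)

    tss_by_chrom: dict[str, set[int]] = {}
    for rec in annotation.itertuples(index=False):
        tss_by_chrom.setdefault(rec.chromosome, set()).add(int(rec.tss))

    instances: list[WindowInstance] = []
    dropped_ambiguous = 0
    dropped_boundary = 0
    seen_tss: set[tuple[str, int, str]] = set()
    for rec in annotation.itertuples(index=False):
        key = (rec.chromosome, int(rec.tss), rec.strand)
        if dedup_positives and key in seen_tss:
            continue
        seen_tss.add(key)
        try:
            window = extract_window(assembly, rec.chromosome, int(rec.tss), rec.strand, params)
        except BoundaryError:
            dropped_boundary += 1
            continue
        except AmbiguousBaseError:
            dropped_ambiguous += 1
            continue
        instances.append(
            WindowInstance(window, 1, rec.chromosome, int(rec.tss), rec.strand, rec.transcript_id)
        )
        anchors = sample_negative_anchors(
            rec,
            tss_by_chrom[rec.chromosome],
            n_negatives_per_positive,
            params,
            assembly,
            rng,
            exclusion_radius,
        )
        for pos in anchors:
            try:
                window = extract_window(assembly, rec.chromosome, pos, rec.strand, params)
            except AmbiguousBaseError:
                dropped_ambiguous += 1
                continue
            instances.append(
                WindowInstance(window, 0, rec.chromosome, pos, rec.strand, rec.transcript_id)
            )

    dataset = LabeledDataset(
        instances,
        provenance={
            "source": "build_dataset",
            "seed": seed,
            "window_params": {
                "upstream_flank": params.upstream_flank,
                "codon_length": params.codon_length,
                "downstream_flank": params.downstream_flank,
            },
            "n_negatives_per_positive": n_negatives_per_positive,
            "dropped_ambiguous": dropped_ambiguous,
            "dropped_boundary": dropped_boundary,
        },
    )
    dataset.provenance["n_positive"] = dataset.n_positive
    dataset.provenance["n_negative"] = dataset.n_negative
    return dataset


def split_by_chromosome(
    dataset: LabeledDataset,
    validation_chromosomes=DEFAULT_VALIDATION_CHROMOSOMES,
    test_chromosomes=DEFAULT_TEST_CHROMOSOMES,
) -> DatasetSplit:
    """Partition a dataset by chromosome into train / validation / test.

    Instances on chromosomes in neither set go to train. The partition is
    exhaustive and exclusive.
    """
    validation_chromosomes = frozenset(str(c) for c in validation_chromosomes)
    test_chromosomes = frozenset(str(c) for c in test_chromosomes)
    if validation_chromosomes & test_chromosomes:
        raise ConfigurationError(
            "validation and test chromosome sets overlap: "
            f"{sorted(validation_chromosomes & test_chromosomes)}"
        )
    parts: dict[str, list[WindowInstance]] = {"train": [], "validation": [], "test": []}
    for inst in dataset.instances:
        if inst.chromosome in validation_chromosomes:
            parts["validation"].append(inst)
        elif inst.chromosome in test_chromosomes:
            parts["test"].append(inst)
        else:
            parts["train"].append(inst)
    prov = dict(dataset.provenance)
    return DatasetSplit(
        train=LabeledDataset(parts["train"], {**prov, "partition": "train"}),
        validation=LabeledDataset(parts["validation"], {**prov, "partition": "validation"}),
        test=LabeledDataset(parts["test"], {**prov, "partition": "test"}),
        validation_chromosomes=validation_chromosomes,
        test_chromosomes=test_chromosomes,
    )


def undersample_majority(
    dataset: LabeledDataset, target_ratio: float = 1.0, seed: int = 0
) -> LabeledDataset:
    """Subsample negatives to ``floor(target_ratio * n_positive)`` per class.

    Positives are untouched; instance order of the survivors is preserved.
    """
    n_pos = dataset.n_positive
    n_neg = dataset.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("dataset must contain both classes")
    n_keep = int(target_ratio * n_pos)
    if n_keep < 1:
        raise ConfigurationError(
            f"target_ratio {target_ratio} yields zero negatives for {n_pos} positives"
        )
    if n_keep >= n_neg:
        return LabeledDataset(list(dataset.instances), dict(dataset.provenance))
    rng = np.random.default_rng(seed)
    neg_idx = [i for i, inst in enumerate(dataset.instances) if inst.label == 0]
    keep = set(rng.choice(neg_idx, size=n_keep, replace=False).tolist())
    instances = [
        inst
        for i, inst in enumerate(dataset.instances)
        if inst.label == 1 or i in keep
    ]
    prov = dict(dataset.provenance)
    prov["undersampled_to_ratio"] = target_ratio
    prov["undersample_seed"] = seed
    return LabeledDataset(instances, prov)


def write_dataset(dataset: LabeledDataset, path) -> None:
    """Write a dataset as CSV plus a JSON manifest sidecar (``<path>.manifest.json``)."""
    dataset.to_frame().to_csv(path, index=False)
    manifest = {
        "n_instances": len(dataset),
        "n_positive": dataset.n_positive,
        "n_negative": dataset.n_negative,
        "provenance": dataset.provenance,
    }
    with open(f"{path}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_dataset(path) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`; validates sequence lengths."""
    try:
        frame = pd.read_csv(
            path, dtype={"sequence": str, "chromosome": str, "transcript_id": str}
        )
    except Exception as exc:  # noqa: BLE001 - normalize to a parse error
        raise DatasetParseError(f"cannot parse dataset file {path}: {exc}") from exc
    required = {"sequence", "label", "chromosome", "anchor", "strand", "transcript_id"}
    missing = required - set(frame.columns)
    if missing:
        raise DatasetParseError(f"dataset file {path} missing columns {sorted(missing)}")
    provenance: dict = {}
    try:
        with open(f"{path}.manifest.json") as fh:
            provenance = json.load(fh).get("provenance", {})
    except FileNotFoundError:
        pass
    instances = []
    expected_len = None
    wp = provenance.get("window_params")
    if wp:
        expected_len = wp["upstream_flank"] + wp["codon_length"] + wp["downstream_flank"]
    for i, row in enumerate(frame.itertuples(index=False)):
        if expected_len is not None and len(row.sequence) != expected_len:
            raise DatasetParseError(
                f"record {i + 1} (line {i + 2}) of {path}: sequence length "
                f"{len(row.sequence)} != expected {expected_len}"
            )
        instances.append(
            WindowInstance(
                row.sequence,
                int(row.label),
                str(row.chromosome),
                int(row.anchor),
                row.strand,
                str(row.transcript_id),
            )
        )
    lengths = {len(inst.sequence) for inst in instances}
    if len(lengths) > 1:
        raise DatasetParseError(f"dataset file {path} mixes sequence lengths {sorted(lengths)}")
    return LabeledDataset(instances, provenance)


DEFAULT_BIOMART_COLUMN_MAP = {
    "transcript_id": "transcript_id",
    "chromosome": "chromosome",
    "strand": "strand",
    "transcript_start": "transcript_start",
    "transcript_end": "transcript_end",
    "tss": "tss",
    "sequence": None,  # optional pre-extracted sequence column
}


def read_biomart_export(path, column_map: dict | None = None):
    """Read a BioMart-style tab-separated export into a transcript annotation.

    ``column_map`` maps canonical field names (keys of
    ``DEFAULT_BIOMART_COLUMN_MAP``) to the file's column headers. Rows with a
    null/empty value in any relevant field are dropped and counted. Strand
    values ``1``/``-1`` (Ensembl numeric convention) are normalized to
    ``+``/``-``.

    Returns ``(annotation, sequences, n_dropped)`` where ``sequences`` is a
    list aligned with the annotation rows when a sequence column is mapped,
    else ``None``.
    """
    cmap = dict(DEFAULT_BIOMART_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = [k for k in ANNOTATION_COLUMNS]
    for field_name in required:
        col = cmap[field_name]
        if col not in frame.columns:
            raise SchemaError(f"annotation file {path} is missing column {col!r}")
    seq_col = cmap.get("sequence")
    relevant = [cmap[f] for f in required] + ([seq_col] if seq_col else [])
    sub = frame[relevant].copy()
    before = len(sub)
    sub = sub.replace("", np.nan).dropna()
    n_dropped = before - len(sub)
    if len(sub) == 0:
        logger.warning("annotation file %s yields no usable rows", path)
    annotation = pd.DataFrame(
        {
            "transcript_id": sub[cmap["transcript_id"]].astype(str).values,
            "chromosome": sub[cmap["chromosome"]].astype(str).values,
            "strand": [
                "+" if s in ("+", "1") else "-" for s in sub[cmap["strand"]].astype(str)
            ],
            "transcript_start": sub[cmap["transcript_start"]].astype(int).values,
            "transcript_end": sub[cmap["transcript_end"]].astype(int).values,
            "tss": sub[cmap["tss"]].astype(int).values,
        }
    )
    sequences = sub[seq_col].astype(str).tolist() if seq_col else None
    return annotation, sequences, n_dropped
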