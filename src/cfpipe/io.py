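"""Fragment and feature-matrix input/output.

Aligned cfDNA fragments travel through the pipeline as a pandas DataFrame
("fragment frame") with one row per fragment and the columns of
:data:`FRAGMENT_COLUMNS`; :class:`FragmentRecord` is the scalar view of one
row. On disk a fragment set is a BED-like TSV with half-open, 0-based
coordinates:

    chrom  start  end  name  mapq  strand  motif4  dupflag

Paired-end BAM/SAM ingestion is also supported (proper pairs, primary
alignments only), yielding the same frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import MiniGenome

logger = logging.getLogger(__name__)

__all__ = [
    "FRAGMENT_COLUMNS",
    "FragmentRecord",
    "frame_from_records",
    "filter_fragments",
    "read_fragments",
    "write_fragments",
    "read_fragments_bam",
    "FeatureBlock",
    "write_feature_matrix",
    "read_feature_matrix",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand", "motif4", "duplicate"]

_VALID_STRANDS = {"+", "-"}
_MOTIF_ALPHABET = set("ACGTN")


class FragmentRecord(NamedTuple):
    """One aligned cfDNA fragment."""

    chrom: str
    start: int
    end: int
    name: str
    mapq: int
    strand: str
    motif4: str
    duplicate: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def frame_from_records(records: Sequence[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(list(records), columns=FRAGMENT_COLUMNS)


def _validate_frame(df: pd.DataFrame, genome: MiniGenome | None, source: str) -> None:
    bad_len = df.index[df["end"].to_numpy() <= df["start"].to_numpy()]
    if len(bad_len):
        raise ValueError(f"{source}: non-positive fragment length at line {bad_len[0] + 1}")
    motif_len = df["motif4"].str.len()
    bad_motif = df.index[(motif_len != 4) | ~df["motif4"].str.fullmatch("[ACGTN]{4}")]
    if len(bad_motif):
        raise ValueError(f"{source}: malformed motif4 at line {bad_motif[0] + 1}")
    bad_strand = df.index[~df["strand"].isin(_VALID_STRANDS)]
    if len(bad_strand):
        raise ValueError(f"{source}: bad strand at line {bad_strand[0] + 1}")
    if genome is not None:
        sizes = genome.sizes()
        unknown = df.index[~df["chrom"].isin(sizes)]
        if len(unknown):
            raise ValueError(
                f"{source}: unknown chromosome {df.loc[unknown[0], 'chrom']!r} "
                f"at line {unknown[0] + 1}"
            )


def filter_fragments(
    df: pd.DataFrame, mapq_min: int = 30, drop_duplicates: bool = True
) -> pd.DataFrame:
    """Keep fragments with ``mapq >= mapq_min`` (inclusive) and, when
    requested, without the PCR-duplicate flag. Idempotent; preserves order."""
    keep = df["mapq"].to_numpy() >= mapq_min
    if drop_duplicates:
        keep &= ~df["duplicate"].to_numpy(dtype=bool)
    return df.loc[keep].reset_index(drop=True)


def read_fragments(
    path: str,
    mapq_min: int = 30,
    drop_duplicates: bool = True,
    genome: MiniGenome | None = None,
) -> pd.DataFrame:
    """Read a BED-like fragment TSV, validate it, and apply the mapping
    quality and duplicate filters. Logs the read/kept counts."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=FRAGMENT_COLUMNS,
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "name": str,
                "mapq": np.int64,
                "strand": str,
                "motif4": str,
                "duplicate": np.int64,
            },
        )
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty fragment file", path)
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed fragment file: {exc}") from exc
    df["duplicate"] = df["duplicate"].astype(bool)
    _validate_frame(df, genome, path)
    kept = filter_fragments(df, mapq_min=mapq_min, drop_duplicates=drop_duplicates)
    logger.info("%s: read %d fragments, kept %d after filters", path, len(df), len(kept))
    return kept


def write_fragments(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["duplicate"] = out["duplicate"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def read_fragments_bam(
    path: str,
    mapq_min: int = 30,
    drop_duplicates: bool = True,
    genome: MiniGenome | None = None,
) -> pd.DataFrame:
    """Build a fragment frame from a paired-end BAM/SAM file.

    Only proper pairs with both mates primary and mapped contribute; each
    pair yields one fragment spanning the outer template coordinates. The
    fragment mapq is the minimum over the two reads ("above threshold for
    either read" is ambiguous in the field; the minimum is the conservative
    reading). The 4-mer is the first four *sequenced* bases of R1, i.e.
    reverse-complemented from the stored sequence when R1 aligns to the
    minus strand. Pairs are buffered by name, so this reader targets
    desk-scale files, not production BAMs.
    """
    import pysam

    pairs: dict[str, dict[int, "pysam.AlignedSegment"]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
            ):
                continue
            pairs.setdefault(read.query_name, {})[1 if read.is_read1 else 2] = read

    records: list[FragmentRecord] = []
    for qname, mates in pairs.items():
        if set(mates) != {1, 2}:
            continue
        r1, r2 = mates[1], mates[2]
        if r1.reference_name != r2.reference_name:
            continue
        start = min(r1.reference_start, r2.reference_start)
        end = max(r1.reference_end, r2.reference_end)
        seq = r1.query_sequence or ""
        motif = (_revcomp(seq[-4:]) if r1.is_reverse else seq[:4]).upper()
        if len(motif) < 4:
            motif = (motif + "NNNN")[:4]
        records.append(
            FragmentRecord(
                chrom=str(r1.reference_name),
                start=int(start),
                end=int(end),
                name=qname,
                mapq=int(min(r1.mapping_quality, r2.mapping_quality)),
                strand="-" if r1.is_reverse else "+",
                motif4=motif,
                duplicate=bool(r1.is_duplicate or r2.is_duplicate),
            )
        )
    df = frame_from_records(records)
    if len(df):
        df = df.sort_values(["chrom", "start", "end", "name"]).reset_index(drop=True)
        _validate_frame(df, genome, path)
    else:
        df = pd.DataFrame(columns=FRAGMENT_COLUMNS)
    kept = filter_fragments(df, mapq_min=mapq_min, drop_duplicates=drop_duplicates)
    logger.info("%s: read %d fragment pairs, kept %d after filters", path, len(df), len(kept))
    return kept


# ---------------------------------------------------------------------------
# feature matrices


@dataclass
class FeatureBlock:
    """A named, ordered block of per-subject features from one dimension.

    ``values`` is subjects x features; ``block_name`` is one of
    ``fragmentation``, ``motif``, ``cnv``, ``tfbs`` (free-form names are
    allowed for derived blocks).
    """

    block_name: str
    feature_names: list[str]
    values: np.ndarray
    subjects: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x features matrix")
        if self.values.shape != (len(self.subjects), len(self.feature_names)):
            raise ValueError(
                f"block {self.block_name}: shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.feature_names)} features"
            )
        if np.isnan(self.values).any():
            raise ValueError(
                f"block {self.block_name}: missing values present; impute before assembly"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.block_name}:{f}" for f in self.feature_names]
        return pd.DataFrame(self.values, index=self.subjects, columns=cols)


def _check_same_subjects(blocks: Sequence[FeatureBlock]) -> list[str]:
    subjects = blocks[0].subjects
    for b in blocks[1:]:
        if b.subjects != subjects:
            raise ValueError(
                f"subject ordering mismatch between blocks "
                f"{blocks[0].block_name!r} and {b.block_name!r}"
            )
    return subjects


def write_feature_matrix(blocks: Sequence[FeatureBlock], path: str) -> None:
    """Write blocks side by side as one TSV; headers are ``block:feature``
    and values carry 12 significant digits, so a round-trip is value-exact
    at that precision."""
    if not blocks:
        raise ValueError("no blocks to write")
    _check_same_subjects(blocks)
    df = pd.concat([b.to_frame() for b in blocks], axis=1)
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_feature_matrix(path: str) -> list[FeatureBlock]:
    df = pd.read_csv(path, sep="\t", index_col="subject")
    subjects = [str(s) for s in df.index]
    blocks: list[FeatureBlock] = []
    order: list[str] = []
    by_block: dict[str, list[str]] = {}
    for col in df.columns:
        block, feature = col.split(":", 1)
        if block not in by_block:
            by_block[block] = []
            order.append(block)
        by_block[block].append(feature)
    for block in order:
        cols = [f"{block}:{f}" for f in by_block[block]]
        blocks.append(
            FeatureBlock(
                block_name=block,
                feature_names=by_block[block],
                values=df[cols].to_numpy(dtype=float),
                subjects=subjects,
            )
        )
    return blocks
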