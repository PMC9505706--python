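"""Taxonomy data model and I/O for QIIME-classic OTU tables and metadata.

The pipeline starts from a tab-separated OTU count table (rows = OTUs,
columns = samples, last column a semicolon-delimited lineage) as produced
by closed-reference OTU picking against SILVA or Greengenes.  OTUs that
could not be assigned at the genus level carry a fallback genus label of
the form ``(<deepest-resolved-label>)`` so that every feature downstream
has a complete six-rank lineage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from taxrisk.errors import (
    ConfigError,
    FormatError,
    LineageParseError,
    ValidationError,
)

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus")

_SILVA_PREFIX = re.compile(r"^D_(\d)__")
_GREENGENES_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

_TAXONOMY_COLUMN_NAMES = {"taxonomy", "consensuslineage", "consensus lineage"}


@dataclass(frozen=True)
class TaxonLineage:
    """Six-rank bacterial lineage, kingdom through genus.

    ``placeholder`` is true when the genus label is a parenthesised
    fallback carrying the deepest resolved rank, e.g. ``(Muribaculaceae)``
    for an OTU resolved only to family.  Bracketed SILVA names such as
    ``[Ruminococcus] gnavus group`` are genuine database labels, not
    placeholders.
    """

    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    resolved_rank: str = "genus"
    placeholder: bool = False

    def __post_init__(self) -> None:
        for rank in RANKS:
            if not getattr(self, rank):
                raise ValidationError(f"lineage rank {rank!r} is empty")
        expect_placeholder = self.genus.startswith("(") and self.genus.endswith(")")
        if self.placeholder != expect_placeholder:
            raise ValidationError(
                f"placeholder flag {self.placeholder} inconsistent with "
                f"genus label {self.genus!r}"
            )

    def labels(self) -> tuple[str, ...]:
        """Rank labels ordered kingdom → genus."""
        return tuple(getattr(self, rank) for rank in RANKS)

    def label_at(self, rank: str) -> str:
        rank = "class_" if rank == "class" else rank
        return getattr(self, rank)


def _detect_dialect(s: str) -> str:
    if _SILVA_PREFIX.match(s.strip()):
        return "silva"
    head = s.strip().lower()
    if any(head.startswith(p) for p in _GREENGENES_PREFIXES):
        return "greengenes"
    # No recognised prefix: bare labels, rank order positional.
    return "bare"


def _strip_prefix(token: str, dialect: str, position: int) -> str:
    token = token.strip()
    if dialect == "silva":
        m = _SILVA_PREFIX.match(token)
        if m:
            return token[m.end():].strip()
        return token
    if dialect == "greengenes":
        low = token.lower()
        for p in _GREENGENES_PREFIXES:
            if low.startswith(p):
                return token[len(p):].strip()
        return token
    return token


def parse_lineage(lineage_string: str, dialect: str = "auto") -> TaxonLineage:
    """Parse a semicolon-delimited taxonomy string into a :class:`TaxonLineage`.

    Unresolved ranks below the deepest database-assigned label are filled
    with ``(<deepest-resolved-label>)``; a seventh (species) field, when
    present, is ignored after genus assignment.

    Parameters
    ----------
    lineage_string:
        1–7 semicolon-separated rank labels, optionally carrying SILVA
        (``D_0__`` …) or Greengenes (``k__`` …) prefixes.
    dialect:
        ``"silva"``, ``"greengenes"``, or ``"auto"`` to detect from the
        prefix of the first field.
    """
    if lineage_string is None or not lineage_string.strip():
        raise LineageParseError("empty lineage string")
    if dialect == "auto":
        dialect = _detect_dialect(lineage_string)
    elif dialect not in ("silva", "greengenes", "bare"):
        raise ConfigError(f"unknown lineage dialect {dialect!r}")

    tokens = [t.strip() for t in lineage_string.strip().strip(";").split(";")]
    if len(tokens) > 7:
        raise LineageParseError(
            f"lineage has {len(tokens)} fields, at most 7 supported: "
            f"{lineage_string!r}"
        )
    labels = [_strip_prefix(t, dialect, i) for i, t in enumerate(tokens)]
    labels = labels[:6]  # species field, if any, is dropped
    labels += [""] * (6 - len(labels))

    resolved_idx = -1
    for i, lab in enumerate(labels):
        if lab and not (lab.startswith("(") and lab.endswith(")")):
            resolved_idx = i
    # Re-parsing serialized output: placeholders were written as empty
    # fields, so a parenthesised label only appears via direct user input;
    # treat it as unresolved and rebuild from the deepest resolved rank.
    if resolved_idx < 0:
        raise LineageParseError(
            f"no resolved rank in lineage {lineage_string!r}"
        )

    filled = list(labels)
    deepest = filled[0]
    for i in range(6):
        lab = filled[i]
        if lab and not (lab.startswith("(") and lab.endswith(")")):
            deepest = lab
        else:
            filled[i] = f"({deepest})"

    placeholder = resolved_idx < 5
    return TaxonLineage(
        kingdom=filled[0],
        phylum=filled[1],
        class_=filled[2],
        order=filled[3],
        family=filled[4],
        genus=filled[5],
        resolved_rank=RANK_NAMES[resolved_idx],
        placeholder=placeholder,
    )


def serialize_lineage(lineage: TaxonLineage, dialect: str = "silva") -> str:
    """Render a lineage back to a prefixed taxonomy string.

    Placeholder (parenthesised) labels serialize as empty fields so that
    ``parse_lineage(serialize_lineage(x))`` reproduces ``x``.
    """
    if dialect not in ("silva", "greengenes"):
        raise ConfigError(f"unknown lineage dialect {dialect!r}")
    out = []
    for i, lab in enumerate(lineage.labels()):
        if lab.startswith("(") and lab.endswith(")"):
            lab = ""
        if dialect == "silva":
            out.append(f"D_{i}__{lab}")
        else:
            out.append(f"{_GREENGENES_PREFIXES[i]}{lab}")
    return ";".join(out)


@dataclass
class OtuTable:
    """Dense sample × OTU count matrix with one lineage per OTU."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus), non-negative ints
    lineages: list[TaxonLineage]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_s, n_o = len(self.sample_ids), len(self.otu_ids)
        if self.counts.shape != (n_s, n_o):
            raise ValidationError(
                f"counts shape {self.counts.shape} != ({n_s}, {n_o})"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValidationError("duplicate sample IDs")
        if len(set(self.otu_ids)) != n_o:
            raise ValidationError("duplicate OTU IDs")
        if len(self.lineages) != n_o:
            raise ValidationError("every OTU needs a lineage")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac, _ = np.modf(self.counts)
            if np.any(frac != 0):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        depths = self.counts.sum(axis=1)
        if np.any(depths <= 0):
            bad = [s for s, d in zip(self.sample_ids, depths) if d <= 0]
            raise ValidationError(f"samples with zero read depth: {bad}")

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.otu_ids
        )


@dataclass
class SampleMetadata:
    """Mapping sample → group label, with levels in first-appearance order."""

    groups: dict[str, str]
    levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.groups.values()))
        if not self.levels:
            self.levels = seen
        missing = set(seen) - set(self.levels)
        if missing:
            raise ValidationError(f"group levels missing from order: {missing}")

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(
                f"samples absent from metadata: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        return np.array([self.groups[s] for s in sample_ids])

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def __len__(self) -> int:
        return len(self.groups)


def _check_genus_consistency(lineages: list[TaxonLineage]) -> None:
    seen: dict[str, TaxonLineage] = {}
    for lin in lineages:
        prev = seen.setdefault(lin.genus, lin)
        if prev.labels() != lin.labels():
            raise ValidationError(
                f"genus {lin.genus!r} maps to conflicting lineages: "
                f"{prev.labels()} vs {lin.labels()}"
            )


def read_otu_table(path, dialect: str = "auto") -> OtuTable:
    """Read a QIIME-classic OTU table (rows = OTUs, last column = taxonomy).

    Leading ``#`` comment lines are skipped; a ``#OTU ID`` line is taken as
    the header.  Counts may be integers or floats with a zero fractional
    part.  Raises :class:`FormatError` naming the offending line on ragged
    rows, negative or fractional counts, or a missing taxonomy column.
    """
    header: list[str] | None = None
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    lineage_strings: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if header is None:
                if line.startswith("#") and not line.lower().startswith("#otu"):
                    continue
                header = line.lstrip("#").split("\t")
                header[0] = header[0].strip() or "OTU ID"
                if len(header) < 3:
                    raise FormatError(
                        f"line {lineno}: header needs id, >=1 sample, taxonomy"
                    )
                if header[-1].strip().lower() not in _TAXONOMY_COLUMN_NAMES:
                    raise FormatError(
                        f"line {lineno}: last column must be 'taxonomy' or "
                        f"'ConsensusLineage', got {header[-1]!r}"
                    )
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            otu_ids.append(fields[0])
            lineage_strings.append(fields[-1])
            row = []
            for j, tok in enumerate(fields[1:-1], start=1):
                try:
                    val = float(tok)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-numeric count {tok!r}"
                    ) from None
                if val < 0:
                    raise FormatError(f"line {lineno}: negative count {tok!r}")
                if not math.isclose(val, round(val), abs_tol=0.0):
                    raise FormatError(f"line {lineno}: fractional count {tok!r}")
                row.append(int(round(val)))
            rows.append(row)

    if header is None or not rows:
        raise FormatError(f"{path}: no data rows")
    if len(set(otu_ids)) != len(otu_ids):
        dupes = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise FormatError(f"duplicate OTU IDs: {dupes[:5]}")

    sample_ids = [h.strip() for h in header[1:-1]]
    if dialect == "auto":
        dialect = _detect_dialect(lineage_strings[0])
    lineages = [parse_lineage(s, dialect) for s in lineage_strings]
    _check_genus_consistency(lineages)

    counts = np.array(rows, dtype=np.int64).T  # file is OTUs × samples
    return OtuTable(sample_ids, otu_ids, counts, lineages)


def write_otu_table(table: OtuTable, path, dialect: str = "silva") -> None:
    """Write an OtuTable in QIIME-classic layout (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for j, otu in enumerate(table.otu_ids):
            counts = "\t".join(str(int(c)) for c in table.counts[:, j])
            fh.write(f"{otu}\t{counts}\t{serialize_lineage(table.lineages[j], dialect)}\n")


def read_metadata(path) -> SampleMetadata:
    """Read a two-column (sample_id, group) TSV with header."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty metadata file") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: metadata needs >=2 columns")
    if df.empty:
        raise FormatError(f"{path}: metadata has no rows")
    sample_col, group_col = df.columns[0], df.columns[1]
    if df[sample_col].duplicated().any():
        dupes = df.loc[df[sample_col].duplicated(), sample_col].tolist()
        raise FormatError(f"duplicate sample IDs in metadata: {dupes[:5]}")
    if df[[sample_col, group_col]].isna().any().any():
        raise FormatError(f"{path}: missing values in metadata")
    groups = dict(zip(df[sample_col], df[group_col]))
    return SampleMetadata(groups)


def write_metadata(metadata: SampleMetadata, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in metadata.groups.items():
            fh.write(f"{s}\t{g}\n")


def write_feature_matrix(profile, path) -> None:
    """Write a per-sample feature matrix as TSV, features sorted, 17-sig-digit values.

    Accepts a GenusProfile / AccumulatedProfile (anything with a ``.values``
    DataFrame) or a plain DataFrame (rows = samples).
    """
    df = profile.values if hasattr(profile, "values") and isinstance(
        getattr(profile, "values"), pd.DataFrame
    ) else profile
    if not isinstance(df, pd.DataFrame):
        raise ConfigError("expected a profile or DataFrame")
    if df.empty:
        raise ValidationError("refusing to write an empty feature matrix")
    df = df.reindex(columns=sorted(df.columns))
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty feature matrix")
    return df
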