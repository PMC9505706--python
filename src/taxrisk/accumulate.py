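"""Hierarchical taxonomic accumulation of genus abundances.

Microbiome count tables are zero-inflated and many OTUs are only loosely
resolved at the genus level.  The encoding implemented here addresses both
at once: genus counts are log2-scaled and normalised to per-sample relative
abundances ``V_G``, and each genus feature is then augmented with the
abundance of its clades at every higher rank, geometrically down-weighted::

    V_ACC(g) = V_G(g) + k1*V_F + k2*V_O + k3*V_C + k4*V_P + k5*V_K

where ``V_F .. V_K`` are the per-sample sums of ``V_G`` over all genera
sharing g's family, order, class, phylum and kingdom label, and
``k_i = 10**-(1+i)`` (0.01 down to 1e-6).  A genus known only as
``(Lachnospiraceae)`` still contributes to — and is weighted by — its
verified family, so imprecisely classified taxa inform the model through
the part of their taxonomy that is certain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from taxrisk.errors import ConfigError, ValidationError
from taxrisk.taxa_io import OtuTable, TaxonLineage

#: weights for (family, order, class, phylum, kingdom), k_i = 10**-(1+i)
ACCUMULATION_WEIGHTS: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)

#: ranks above genus, nearest first, matching ACCUMULATION_WEIGHTS order
_UPPER_RANKS = ("family", "order", "class_", "phylum", "kingdom")


@dataclass
class GenusProfile:
    """Per-sample genus relative abundances after log2 scaling.

    ``values`` is a samples × genera DataFrame; every row sums to 1 and all
    entries are non-negative.
    """

    values: pd.DataFrame
    lineages: dict[str, TaxonLineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < 0).any():
            raise ValidationError("negative abundance in genus profile")
        sums = v.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("per-sample abundances must sum to 1")
        missing = set(self.values.columns) - set(self.lineages)
        if missing:
            raise ValidationError(f"genera without lineage: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AccumulatedProfile:
    """Per-sample accumulated genus features (``V_ACC``)."""

    values: pd.DataFrame
    lineages: dict[str, TaxonLineage] = field(default_factory=dict)
    weights: tuple[float, ...] = ACCUMULATION_WEIGHTS

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def collapse_to_genus(
    table: OtuTable,
) -> tuple[pd.DataFrame, dict[str, TaxonLineage]]:
    """Sum OTU counts sharing a genus label into one feature per genus.

    Returns the samples × genera integer count matrix and the genus →
    lineage map.  Two OTUs with the same genus label but conflicting
    upper ranks are an error: a genus feature must have one lineage.
    """
    lineage_of: dict[str, TaxonLineage] = {}
    for otu, lin in zip(table.otu_ids, table.lineages):
        prev = lineage_of.setdefault(lin.genus, lin)
        if prev.labels() != lin.labels():
            raise ValidationError(
                f"genus {lin.genus!r} has conflicting lineages "
                f"(OTU {otu}): {prev.labels()} vs {lin.labels()}"
            )

    genera = [lin.genus for lin in table.lineages]
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=genera)
    collapsed = df.T.groupby(level=0, sort=False).sum().T
    return collapsed, lineage_of


def log_and_normalize(
    genus_counts: pd.DataFrame,
    lineages: dict[str, TaxonLineage] | None = None,
) -> GenusProfile:
    """log2(count + 1), then scale each sample's vector to sum to one.

    The +1 pseudocount keeps zero counts at exactly zero while compressing
    the heavy right tail of microbiome counts; normalisation makes samples
    comparable regardless of sequencing depth.
    """
    counts = genus_counts.to_numpy()
    if (counts < 0).any():
        raise ValidationError("negative counts")
    logged = np.log2(counts + 1.0)
    totals = logged.sum(axis=1)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(genus_counts.index, totals) if t <= 0]
        raise ValidationError(f"all-zero samples cannot be normalised: {bad}")
    values = pd.DataFrame(
        logged / totals[:, None],
        index=genus_counts.index,
        columns=genus_counts.columns,
    )
    return GenusProfile(values, dict(lineages or {}))


def accumulate(
    profile: GenusProfile,
    weights: tuple[float, ...] = ACCUMULATION_WEIGHTS,
) -> AccumulatedProfile:
    """Add down-weighted clade sums (family → kingdom) to every genus value.

    Clade sums include the genus's own ``V_G`` and are computed per sample
    independently; the result is order-independent in both samples and
    features.
    """
    if len(weights) != len(_UPPER_RANKS):
        raise ConfigError(
            f"need {len(_UPPER_RANKS)} weights (family..kingdom), "
            f"got {len(weights)}"
        )
    genera = profile.features
    missing = [g for g in genera if g not in profile.lineages]
    if missing:
        raise ValidationError(f"no lineage for features: {missing[:5]}")

    V = profile.values.to_numpy(dtype=float)
    acc = V.copy()
    for rank, k in zip(_UPPER_RANKS, weights):
        labels = [profile.lineages[g].label_at(rank) for g in genera]
        codes, _ = pd.factorize(np.asarray(labels, dtype=object))
        n_codes = codes.max() + 1
        onehot = np.zeros((len(genera), n_codes))
        onehot[np.arange(len(genera)), codes] = 1.0
        clade_sums = V @ onehot  # samples × clades
        acc += k * clade_sums[:, codes]

    values = pd.DataFrame(acc, index=profile.sample_ids, columns=genera)
    return AccumulatedProfile(values, dict(profile.lineages), tuple(weights))


def preprocess(
    table: OtuTable,
    weights: tuple[float, ...] = ACCUMULATION_WEIGHTS,
) -> AccumulatedProfile:
    """Full encoding pipeline: collapse to genus, log2-normalise, accumulate."""
    counts, lineages = collapse_to_genus(table)
    return accumulate(log_and_normalize(counts, lineages), weights)
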