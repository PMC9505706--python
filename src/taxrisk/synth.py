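"""Synthetic 16S cohorts with known ground truth.

The generator emulates the statistical shape of genus-level stool
microbiome tables: a random six-rank taxonomy with a configurable fraction
of genera resolved only to family (placeholder labels), heavy-tailed
log-normal baseline abundances, per-genus zero-inflation, multinomial read
sampling at realistic depths, and planted case/control fold changes of the
magnitudes seen in gut-disease case/control studies (23-, 13-, 7-fold
increases; 0.17- to 0.34-fold depletions).  A transfer preset adds four
diet arms (Normal, HFD, NFE, NFW) under a shared host-shift factor so that
cross-cohort scoring — including feature-alignment loss — can be exercised
end to end.

Everything is a deterministic function of the spec and a seed: the
taxonomy, baseline means and planted-genus assignment derive from
``spec.seed`` (so clinical and transfer cohorts share a genus universe),
while sample-level noise derives from the per-call seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from taxrisk.errors import ConfigError, ValidationError
from taxrisk.taxa_io import OtuTable, SampleMetadata, TaxonLineage

#: planted case/control fold changes: three enriched, four depleted genera
DEFAULT_FOLD_CHANGES: tuple[float, ...] = (23.0, 13.0, 7.0, 0.17, 0.27, 0.32, 0.34)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Taxonomy sizes give one kingdom and the number of labels per lower
    rank; each label's parent is drawn uniformly.  ``baseline_sigma`` is
    the sd of genus log-abundance means (heavy right tail, as in real
    stool tables); ``sample_sigma`` the per-sample log-normal dispersion;
    ``zero_inflation`` the per-genus probability of a structural zero.
    Depths are uniform integers over ``depth_range`` (minimum 1099, the
    rarefaction floor of the emulated study).
    """

    n_phyla: int = 6
    n_classes: int = 10
    n_orders: int = 15
    n_families: int = 30
    n_genera: int = 150
    placeholder_fraction: float = 0.1
    group_sizes: tuple[tuple[str, int], ...] = (("HC", 395), ("IBD", 109))
    case_groups: tuple[str, ...] = ("IBD",)
    planted_folds: tuple[float, ...] = DEFAULT_FOLD_CHANGES
    baseline_sigma: float = 2.0
    sample_sigma: float = 0.7
    zero_inflation: float = 0.3
    depth_range: tuple[int, int] = (1099, 4000)
    transfer_group_sizes: tuple[tuple[str, int], ...] = (
        ("Normal", 8), ("HFD", 8), ("NFE", 8), ("NFW", 8))
    host_shift_sigma: float = 0.5
    absent_fraction: float = 0.1
    nfe_reversal: float = 0.8
    nfw_reversal: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1:
            raise ConfigError("need at least one genus")
        if not 0 <= self.zero_inflation < 1:
            raise ConfigError("zero_inflation must be in [0, 1)")
        if any(f <= 0 for f in self.planted_folds):
            raise ConfigError("fold changes must be positive")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigError("invalid depth range")
        for name, r in (("nfe_reversal", self.nfe_reversal),
                        ("nfw_reversal", self.nfw_reversal)):
            if not 0 <= r <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


def clinical_spec(n_control: int = 395, n_case: int = 109,
                  **overrides) -> SyntheticSpec:
    """Case/control preset at the emulated clinical cohort scale."""
    return SyntheticSpec(
        group_sizes=(("HC", n_control), ("IBD", n_case)),
        case_groups=("IBD",), **overrides,
    )


def rat_spec(**overrides) -> SyntheticSpec:
    """Preset for the four-arm transfer cohort.

    Identical to :func:`clinical_spec` so the rat arms share the clinical
    genus universe; :func:`simulate_transfer_groups` reads the arm sizes
    from ``transfer_group_sizes``.
    """
    return clinical_spec(**overrides)


def build_taxonomy(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[list[str], dict[str, TaxonLineage]]:
    """Draw a random taxonomy; returns (genus names, genus → lineage).

    A ``placeholder_fraction`` of genera are unresolved and named
    ``(<their family>)``; placeholders landing in the same family merge
    into one genus feature, as they would in a real table.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    phyla = [f"Phylum{i:02d}" for i in range(spec.n_phyla)]
    classes = [f"Class{i:02d}" for i in range(spec.n_classes)]
    orders = [f"Order{i:02d}" for i in range(spec.n_orders)]
    families = [f"Family{i:02d}" for i in range(spec.n_families)]

    class_parent = rng.integers(0, spec.n_phyla, spec.n_classes)
    order_parent = rng.integers(0, spec.n_classes, spec.n_orders)
    family_parent = rng.integers(0, spec.n_orders, spec.n_families)
    genus_family = rng.integers(0, spec.n_families, spec.n_genera)
    is_placeholder = rng.random(spec.n_genera) < spec.placeholder_fraction

    genus_names: list[str] = []
    lineages: dict[str, TaxonLineage] = {}
    for g in range(spec.n_genera):
        fam = genus_family[g]
        order = family_parent[fam]
        cls = order_parent[order]
        phy = class_parent[cls]
        if is_placeholder[g]:
            name = f"({families[fam]})"
        else:
            name = f"Genus{g:03d}"
        if name in lineages:  # merged placeholder within one family
            continue
        lineages[name] = TaxonLineage(
            kingdom="Bacteria", phylum=phyla[phy], class_=classes[cls],
            order=orders[order], family=families[fam], genus=name,
            resolved_rank="family" if is_placeholder[g] else "genus",
            placeholder=bool(is_placeholder[g]),
        )
        genus_names.append(name)
    if not genus_names:
        raise ValidationError("taxonomy draw produced no genera")
    return genus_names, lineages


def _structure(spec: SyntheticSpec):
    """Seed-stable study structure: taxonomy, baselines, planted genera."""
    genus_names, lineages = build_taxonomy(spec)
    n = len(genus_names)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))
    mu = rng.normal(0.0, spec.baseline_sigma, n)
    # plant effects on mid-abundance resolved genera so the fold change is
    # neither lost in sampling noise nor dominated by renormalisation
    candidates = [i for i in range(n)
                  if abs(mu[i]) <= 1.0 and not lineages[genus_names[i]].placeholder]
    if len(candidates) < len(spec.planted_folds):
        candidates = list(range(n))
    chosen = rng.choice(candidates, size=len(spec.planted_folds), replace=False)
    planted = {genus_names[i]: f for i, f in zip(chosen, spec.planted_folds)}
    return genus_names, lineages, mu, planted


def planted_genera(spec: SyntheticSpec) -> dict[str, float]:
    """Ground truth: genus → planted case/control fold change."""
    return dict(_structure(spec)[3])


def _draw_samples(rng, spec, mu_eff, n_samples, prefix):
    """Zero-inflated log-normal means → multinomial counts, one row per sample."""
    n_genera = len(mu_eff)
    rows = np.empty((n_samples, n_genera), dtype=np.int64)
    ids = []
    base_mean = np.exp(mu_eff)
    for i in range(n_samples):
        depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
        for attempt in range(100):
            noise = rng.lognormal(0.0, spec.sample_sigma, n_genera)
            m = base_mean * noise
            m[rng.random(n_genera) < spec.zero_inflation] = 0.0
            if m.sum() > 0:
                break
        else:
            raise ValidationError("could not draw a nonzero sample in 100 tries")
        rows[i] = rng.multinomial(depth, m / m.sum())
        ids.append(f"{prefix}{i:03d}")
    return rows, ids


def _assemble_table(genus_names, lineages, blocks, id_blocks, group_of):
    counts = np.vstack(blocks)
    sample_ids = [s for ids in id_blocks for s in ids]
    otu_ids = [f"OTU{i:04d}" for i in range(len(genus_names))]
    table = OtuTable(sample_ids, otu_ids, counts,
                     [lineages[g] for g in genus_names])
    metadata = SampleMetadata({s: group_of[s] for s in sample_ids})
    return table, metadata


def simulate_cohort(
    spec: SyntheticSpec, seed: int = 0, groups: list[str] | None = None
) -> tuple[OtuTable, SampleMetadata]:
    """Simulate the case/control cohort defined by ``spec.group_sizes``.

    Case groups have their planted genera's mean abundances multiplied by
    the planted fold changes before zero-inflation and multinomial read
    sampling.  Same spec + seed reproduces the table exactly.
    """
    genus_names, lineages, mu, planted = _structure(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    blocks, id_blocks, group_of = [], [], {}
    for group, n in spec.group_sizes:
        if groups is not None and group not in groups:
            continue
        mu_eff = mu.copy()
        if group in spec.case_groups:
            for g, fold in planted.items():
                mu_eff[genus_names.index(g)] += np.log(fold)
        rows, ids = _draw_samples(rng, spec, mu_eff, n, f"{group}_")
        blocks.append(rows)
        id_blocks.append(ids)
        group_of.update({s: group for s in ids})
    if not blocks:
        raise ConfigError("no groups selected")
    return _assemble_table(genus_names, lineages, blocks, id_blocks, group_of)


def simulate_transfer_groups(
    spec: SyntheticSpec, seed: int = 0
) -> tuple[OtuTable, SampleMetadata]:
    """Simulate the four-arm transfer cohort (Normal, HFD, NFE, NFW).

    All arms share a host-shift: per-genus log-normal factors (sd
    ``host_shift_sigma``) plus an ``absent_fraction`` of genera missing
    entirely, emulating a different host species.  HFD applies the planted
    disease-direction effects at full strength; NFE attenuates them by
    ``nfe_reversal`` (0.8 → mostly reverted toward Normal); NFW by
    ``nfw_reversal`` (0.0 → effects retained).
    """
    genus_names, lineages, mu, planted = _structure(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    n = len(genus_names)
    host_shift = rng.normal(0.0, spec.host_shift_sigma, n)
    absent = rng.random(n) < spec.absent_fraction
    mu_host = mu + host_shift
    mu_host[absent] = -np.inf  # genus not carried by this host

    retention = {"Normal": 0.0, "HFD": 1.0,
                 "NFE": 1.0 - spec.nfe_reversal, "NFW": 1.0 - spec.nfw_reversal}
    blocks, id_blocks, group_of = [], [], {}
    for group, n_animals in spec.transfer_group_sizes:
        mu_eff = mu_host.copy()
        r = retention[group]
        if r > 0:
            for g, fold in planted.items():
                mu_eff[genus_names.index(g)] += r * np.log(fold)
        rows, ids = _draw_samples(rng, spec, np.where(
            np.isneginf(mu_eff), -np.inf, mu_eff), n_animals, f"{group}_")
        blocks.append(rows)
        id_blocks.append(ids)
        group_of.update({s: group for s in ids})

    keep = ~absent  # drop host-absent genera from the table entirely
    counts = np.vstack(blocks)[:, keep]
    kept_names = [g for g, k in zip(genus_names, keep) if k]
    sample_ids = [s for ids in id_blocks for s in ids]
    otu_ids = [f"OTU{i:04d}" for i, k in enumerate(keep) if k]
    table = OtuTable(sample_ids, otu_ids, counts,
                     [lineages[g] for g in kept_names])
    metadata = SampleMetadata({s: group_of[s] for s in sample_ids})
    return table, metadata
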