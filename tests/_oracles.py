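"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

RANK_ATTRS = ("family", "order", "class_", "phylum", "kingdom")


def accumulate_bruteforce(values: pd.DataFrame, lineages: dict,
                          weights=(1e-2, 1e-3, 1e-4, 1e-5, 1e-6)) -> pd.DataFrame:
    """Nested-loop accumulation: for each sample and genus, walk every rank
    and sum V_G over the genera sharing that rank's label."""
    out = values.copy().astype(float)
    genera = list(values.columns)
    for s in values.index:
        row = values.loc[s]
        for g in genera:
            acc = row[g]
            for k, rank in zip(weights, RANK_ATTRS):
                label = getattr(lineages[g], rank)
                clade_sum = 0.0
                for h in genera:
                    if getattr(lineages[h], rank) == label:
                        clade_sum += row[h]
                acc += k * clade_sum
            out.loc[s, g] = acc
    return out


def random_profile(seed: int, n_samples: int = 20, n_genera: int = 50):
    """Random multi-family GenusProfile ingredients (values sum to 1)."""
    from taxrisk.taxa_io import TaxonLineage

    rng = np.random.default_rng(seed)
    n_fam, n_ord, n_cls, n_phy = 8, 5, 3, 2
    fam_of = rng.integers(0, n_fam, n_genera)
    ord_of = rng.integers(0, n_ord, n_fam)
    cls_of = rng.integers(0, n_cls, n_ord)
    phy_of = rng.integers(0, n_phy, n_cls)
    lineages = {}
    for g in range(n_genera):
        f = fam_of[g]
        o = ord_of[f]
        c = cls_of[o]
        p = phy_of[c]
        lineages[f"g{g}"] = TaxonLineage(
            "Bacteria", f"p{p}", f"c{c}", f"o{o}", f"f{f}", f"g{g}")
    raw = rng.gamma(0.5, size=(n_samples, n_genera)) * (
        rng.random((n_samples, n_genera)) > 0.3)
    raw[raw.sum(axis=1) == 0, 0] = 1.0
    vals = raw / raw.sum(axis=1, keepdims=True)
    values = pd.DataFrame(vals, index=[f"s{i}" for i in range(n_samples)],
                          columns=[f"g{g}" for g in range(n_genera)])
    return values, lineages


def mwu_permutation_pvalue(x, y) -> float:
    """Two-sided MWU p by full enumeration of label assignments (oracle)."""
    import itertools
    from scipy.stats import rankdata

    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    mu = n * len(y) / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        u = sum(ranks[i] for i in idx) - n * (n + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def permanova_f_bruteforce(dist: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F via explicit among/within sum-of-squares loops."""
    n = len(labels)
    groups = sorted(set(labels))
    d2 = dist ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_g = sum(d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1:])
        ss_within += ss_g / len(idx)
    ss_among = ss_total - ss_within
    a = len(groups)
    return (ss_among / (a - 1)) / (ss_within / (n - a))
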