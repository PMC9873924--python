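"""Normalisation, QC rules, gene-set filtering and binned-control module scores.

Module scores follow the binned-control convention: the mean log-normalised
expression of a gene set in each spot, minus the mean of a control pool of
genes sampled from expression bins matched to the set genes (24 equal-
frequency bins on mean expression, 100 controls per set gene by default).
Scores are bit-for-bit reproducible given the matrix, the sets, ``nbin``,
``nctrl`` and a seed.

Log-CP10K normalisation stands in for variance-stabilising transforms; the
zonation statistics downstream are computed per sample, so no cross-sample
integration is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection


@dataclass(frozen=True)
class NormalizedMatrix:
    """Spots x genes log-normalised expression."""

    spot_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite values in normalised matrix")
        object.__setattr__(self, "values", values)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]


@dataclass(frozen=True)
class GeneBins:
    """Equal-frequency expression bins: gene id -> bin index in [0, nbin)."""

    assignment: dict[str, int]
    nbin: int

    def members(self, bin_index: int, gene_order: Sequence[str]) -> list[str]:
        return [g for g in gene_order if self.assignment[g] == bin_index]


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Per-spot log normalisation: ``ln(1 + scale * count / spot_total)``.

    Spots with zero total get all-zero rows and trigger a warning.
    """
    totals = counts.counts.sum(axis=1).astype(float)
    zero = totals == 0
    if zero.all():
        raise ValueError("all spots have zero total counts")
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} spot(s) with zero total counts; rows set to 0",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    values = np.log1p(scale * counts.counts / safe[:, None])
    values[zero] = 0.0
    return NormalizedMatrix(counts.spot_ids, counts.gene_ids, values)


def mito_spot_filter(
    counts: CountMatrix,
    mito_prefix: str = "mt-",
    top_fraction: float = 0.10,
) -> list[str]:
    """Drop the spots with the highest mitochondrial UMI fraction.

    Removes the ``ceil(top_fraction * n)`` spots with the largest fraction of
    counts on genes whose symbol starts with ``mito_prefix``; ties are broken
    by spot id so that the lowest ids are retained.  If no gene matches the
    prefix a warning is issued and every spot is retained.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    mito_cols = [i for i, g in enumerate(counts.gene_ids) if g.startswith(mito_prefix)]
    if not mito_cols:
        warnings.warn(
            f"no gene matches mitochondrial prefix {mito_prefix!r}; "
            "all spots retained",
            stacklevel=2,
        )
        return list(counts.spot_ids)
    totals = counts.counts.sum(axis=1).astype(float)
    mito = counts.counts[:, mito_cols].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1.0), 0.0)
    n_remove = math.ceil(top_fraction * counts.n_spots)
    # removal order: highest fraction first, then highest spot id first
    order = sorted(range(counts.n_spots), key=lambda i: counts.spot_ids[i], reverse=True)
    order.sort(key=lambda i: frac[i], reverse=True)  # stable on the id order
    removed = set(order[:n_remove])
    return [s for i, s in enumerate(counts.spot_ids) if i not in removed]


def detection_matrix(norm: NormalizedMatrix) -> pd.DataFrame:
    """Binarise expression: detected iff strictly above the per-gene median.

    The median is taken per gene across all spots of the sample; with the
    strict inequality a constant gene is detected nowhere.
    """
    medians = np.median(norm.values, axis=0)
    detected = norm.values > medians[None, :]
    return pd.DataFrame(detected, index=list(norm.spot_ids), columns=list(norm.gene_ids))


def filter_gene_sets(
    sets: GeneSetCollection,
    universe: Sequence[str],
    min_n: int = 20,
    max_n: int = 250,
) -> GeneSetCollection:
    """Intersect each set with the data universe and keep sets by size.

    A set is retained iff ``min_n <= |set ∩ universe| <= max_n``; the retained
    set is the intersection itself (order of first occurrence preserved).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    kept: dict[str, tuple[str, ...]] = {}
    for name, genes in sets:
        present = tuple(g for g in genes if g in universe_set)
        if min_n <= len(present) <= max_n:
            kept[name] = present
    return GeneSetCollection(kept)


def bin_genes(norm: NormalizedMatrix, nbin: int = 24) -> GeneBins:
    """Equal-frequency binning of genes on mean expression across spots.

    Genes are ranked by mean log-normalised value (ties broken by gene id
    ascending) and split into ``nbin`` bins whose sizes differ by at most 1.
    """
    n_genes = len(norm.gene_ids)
    if nbin > n_genes:
        raise ValueError(f"nbin={nbin} exceeds number of genes ({n_genes})")
    means = norm.values.mean(axis=0)
    order = sorted(range(n_genes), key=lambda i: (means[i], norm.gene_ids[i]))
    assignment: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.asarray(order), nbin)):
        for i in chunk:
            assignment[norm.gene_ids[int(i)]] = b
    return GeneBins(assignment, nbin)


def module_score(
    norm: NormalizedMatrix,
    genes: Sequence[str],
    bins: GeneBins,
    nctrl: int = 100,
    seed: int | np.random.SeedSequence = 0,
    set_name: str = "<unnamed>",
) -> np.ndarray:
    """Binned-control module score per spot for one gene set.

    For each set gene, ``min(nctrl, bin size)`` control genes are sampled
    uniformly without replacement from its expression bin (the set genes
    themselves are eligible controls).  The control pool is the multiset
    union over set genes; the score of a spot is the mean value over the set
    genes minus the mean over the control pool.  One seeded generator drives
    the call, sub-streamed per set gene in set order, so results do not
    depend on how many other sets are scored.
    """
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    set_idx = [gene_index[g] for g in genes if g in gene_index]
    set_genes = [g for g in genes if g in gene_index]
    if not set_idx:
        raise ValueError(f"gene set {set_name!r} has no genes in the matrix")
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    streams = root.spawn(len(set_genes))
    # bin membership in gene-id order, resolved once
    by_bin: dict[int, list[int]] = {}
    for g in sorted(bins.assignment):
        if g in gene_index:
            by_bin.setdefault(bins.assignment[g], []).append(gene_index[g])
    ctrl_idx: list[int] = []
    for g, stream in zip(set_genes, streams):
        members = by_bin[bins.assignment[g]]
        k = min(nctrl, len(members))
        rng = np.random.default_rng(stream)
        chosen = rng.choice(len(members), size=k, replace=False)
        ctrl_idx.extend(members[j] for j in chosen)
    set_mean = norm.values[:, set_idx].mean(axis=1)
    ctrl_mean = norm.values[:, ctrl_idx].mean(axis=1)
    return set_mean - ctrl_mean


def module_score_matrix(
    norm: NormalizedMatrix,
    sets: GeneSetCollection,
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every set of a collection; spots x sets DataFrame.

    Each set receives an independent sub-stream derived from ``seed`` by its
    position in the collection, so adding sets never perturbs existing scores.
    """
    bins = bin_genes(norm, nbin=nbin)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(sets))
    scores = {}
    for (name, genes), stream in zip(sets, streams):
        scores[name] = module_score(
            norm, genes, bins, nctrl=nctrl, seed=stream, set_name=name
        )
    return pd.DataFrame(scores, index=list(norm.spot_ids))
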