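"""Synthetic zonated-lobule spatial transcriptomics.

Spots sit on a hexagonal Visium-style lattice.  Portal and central anchor
spots define a continuous zonation coordinate ``z = d_c / (d_c + d_p)``
(distances to the nearest central and portal anchor), so ``z = 1`` at portal
anchors and ``z = 0`` at central anchors.  Gene means follow

    mean(s, g) = L_s * exp(beta0 + b1 * (2 z(s) - 1) + g_eff)

with a log-normal library-size factor ``L_s`` and negative-binomial counts
of dispersion ``theta`` (variance = mean + mean^2 / theta).  In the sham
condition ``b1 = beta1`` and ``g_eff = 0``; under cancer ``b1`` becomes the
archetype's cancer amplitude (``rho * beta1`` unless overridden) and
``g_eff = gamma``.  Amplitudes act linearly in ``(2 z - 1) in [-1, 1]``, so
``beta1`` is the half-range log fold-change and oracles have closed forms.

One seed sequence drives each sample bundle, sub-streamed per gene, so
adding genes never perturbs existing genes' draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import SpotGeometry, build_geometry, hex_full_lattice
from .io import (
    CountMatrix,
    GeneSetCollection,
    PositionsTable,
    write_counts_triplet,
    write_gmt,
    write_table,
    write_tissue_positions,
)

ARCHETYPES = (
    "MARKER_PORTAL",
    "MARKER_CENTRAL",
    "SET_RETAINED",
    "SET_LOST",
    "SET_INDUCED",
    "SET_INTERMEDIATE",
    "SET_FLAT",
    "BACKGROUND",
)


@dataclass(frozen=True)
class GeneSpec:
    """Programmed generative parameters for one gene."""

    gene_id: str
    archetype: str
    beta0: float  # baseline natural-log mean
    beta1: float = 0.0  # zonation amplitude (half-range log-fold, portal positive)
    gamma: float = 0.0  # cancer global log-fold
    rho: float = 1.0  # cancer zonation-retention multiplier
    theta: float = 10.0  # negative-binomial dispersion
    beta1_cancer: float | None = None  # overrides rho * beta1 when set

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")

    def cancer_amplitude(self) -> float:
        return self.beta1_cancer if self.beta1_cancer is not None else self.rho * self.beta1


@dataclass(frozen=True)
class SimConfig:
    """Lattice, library-size and seeding parameters for one sample."""

    rows: int = 30
    cols: int = 50
    pitch_um: float = 100.0
    condition: str = "sham"
    lib_mu: float = 0.0
    lib_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in {"sham", "cancer"}:
            raise ValueError("condition must be 'sham' or 'cancer'")
        if self.rows * self.cols < 100:
            raise ValueError("lattice must contain at least 100 spots")


@dataclass(frozen=True)
class LobuleLayout:
    """Spot geometry plus anchors and the zonation coordinate per spot."""

    geometry: SpotGeometry
    portal_anchors: frozenset[str]
    central_anchors: frozenset[str]
    z: np.ndarray  # aligned with geometry.spot_ids, in [0, 1], 1 = portal-adjacent

    def __post_init__(self) -> None:
        if self.portal_anchors & self.central_anchors:
            raise ValueError("portal and central anchors overlap")
        z = np.asarray(self.z, dtype=float)
        if z.shape != (len(self.geometry),):
            raise ValueError("z length does not match geometry")
        if np.any(z < 0) or np.any(z > 1):
            raise ValueError("z must lie in [0, 1]")
        object.__setattr__(self, "z", z)


def compute_z(
    geometry: SpotGeometry,
    portal_anchors: Sequence[str],
    central_anchors: Sequence[str],
) -> np.ndarray:
    """Zonation coordinate z = d_c / (d_c + d_p) for every spot."""
    xy = np.column_stack([geometry.x_um, geometry.y_um])
    idx = geometry._id_to_index
    p_xy = xy[[idx[s] for s in portal_anchors]]
    c_xy = xy[[idx[s] for s in central_anchors]]
    d_p = np.sqrt(((xy[:, None, :] - p_xy[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    d_c = np.sqrt(((xy[:, None, :] - c_xy[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    denom = d_c + d_p
    # a spot cannot be both anchors at once, so denom == 0 never happens
    return d_c / denom


def build_layout(
    rows: int,
    cols: int,
    pitch_um: float,
    n_portal: int,
    n_central: int,
    seed: int,
) -> LobuleLayout:
    """Sample interleaved portal/central anchors on a full lattice.

    Anchor candidates live on a coarse sublattice (even array rows); anchors
    are accepted greedily in alternating portal/central order with a minimum
    pairwise separation of 3 * pitch, which keeps the two vein systems
    interleaved the way lobules tile the tissue.
    """
    if n_portal < 1 or n_central < 1:
        raise ValueError("need at least one anchor of each type")
    geometry = build_geometry(hex_full_lattice(rows, cols), pitch_um)
    rng = np.random.default_rng(seed)
    coarse = [
        i for i in range(len(geometry)) if geometry.array_row[i] % 2 == 0
    ]
    candidates = [coarse[j] for j in rng.permutation(len(coarse))]
    xy = np.column_stack([geometry.x_um, geometry.y_um])
    chosen: list[int] = []
    portal: list[str] = []
    central: list[str] = []
    want_portal = True
    min_sep = 3.0 * pitch_um
    for i in candidates:
        if len(portal) >= n_portal and len(central) >= n_central:
            break
        if chosen and np.min(np.hypot(*((xy[chosen] - xy[i]).T))) < min_sep:
            continue
        if want_portal and len(portal) < n_portal:
            portal.append(geometry.spot_ids[i])
        elif len(central) < n_central:
            central.append(geometry.spot_ids[i])
        elif len(portal) < n_portal:
            portal.append(geometry.spot_ids[i])
        chosen.append(i)
        want_portal = not want_portal
    if len(portal) < n_portal or len(central) < n_central:
        raise ValueError(
            f"could not place {n_portal} portal + {n_central} central anchors with "
            f"separation >= {min_sep:.0f} um on a {rows} x {cols} lattice; "
            "reduce the anchor counts or enlarge the lattice"
        )
    z = compute_z(geometry, portal, central)
    return LobuleLayout(geometry, frozenset(portal), frozenset(central), z)


def simulate_counts(
    layout: LobuleLayout,
    specs: Sequence[GeneSpec],
    config: SimConfig,
) -> tuple[CountMatrix, PositionsTable]:
    """Draw negative-binomial counts for every gene on the layout."""
    if not specs:
        raise ValueError("no gene specs supplied")
    n_spots = len(layout.geometry)
    root = np.random.SeedSequence(config.seed)
    lib_stream, *gene_streams = root.spawn(1 + len(specs))
    lib_rng = np.random.default_rng(lib_stream)
    lib = lib_rng.lognormal(config.lib_mu, config.lib_sigma, size=n_spots)
    u = 2.0 * layout.z - 1.0
    cancer = config.condition == "cancer"
    counts = np.empty((n_spots, len(specs)), dtype=np.int64)
    for j, (spec, stream) in enumerate(zip(specs, gene_streams)):
        b1 = spec.cancer_amplitude() if cancer else spec.beta1
        g_eff = spec.gamma if cancer else 0.0
        mean = lib * np.exp(spec.beta0 + b1 * u + g_eff)
        if not np.all(np.isfinite(mean)):
            raise ValueError(f"non-finite mean for gene {spec.gene_id!r}")
        rng = np.random.default_rng(stream)
        p = spec.theta / (spec.theta + mean)
        counts[:, j] = rng.negative_binomial(spec.theta, p)
    positions = PositionsTable(
        tuple(layout.geometry.spot_ids),
        np.ones(n_spots, dtype=bool),
        layout.geometry.array_row.copy(),
        layout.geometry.array_col.copy(),
        layout.geometry.y_um.copy(),
        layout.geometry.x_um.copy(),
    )
    matrix = CountMatrix(
        tuple(layout.geometry.spot_ids),
        tuple(s.gene_id for s in specs),
        counts,
    )
    return matrix, positions


# ---------------------------------------------------------------------------
# default two-condition scenario
# ---------------------------------------------------------------------------

#: programmed zone-differential signs per archetype set, (sham, cancer)
TRUTH_SIGNS = {
    "RETAINED": ("+", "+"),
    "LOST": ("-", "0"),
    "INDUCED": ("0", "+"),
    "FLAT": ("0", "0"),
}


def default_gene_specs(
    seed: int,
    n_background: int = 2500,
    set_size: int = 25,
) -> tuple[list[GeneSpec], GeneSetCollection]:
    """Markers, four archetype sets and background genes with drawn baselines.

    Baselines are drawn once from the scenario seed so the same gene universe
    is shared by every sample of the scenario.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    specs: list[GeneSpec] = [
        GeneSpec("Alb", "MARKER_PORTAL", beta0=2.5, beta1=1.5),
        GeneSpec("Cyp2e1", "MARKER_CENTRAL", beta0=2.5, beta1=-1.5),
    ]
    sets: dict[str, tuple[str, ...]] = {}

    def draw_beta0() -> float:
        return float(rng.uniform(-1.0, 2.0))

    def add_set(prefix: str, archetype: str, **kw) -> None:
        genes = []
        for i in range(set_size):
            gid = f"{prefix}{i + 1:03d}"
            specs.append(GeneSpec(gid, archetype, beta0=draw_beta0(), **kw))
            genes.append(gid)
        sets[prefix] = tuple(genes)

    add_set("RETAINED", "SET_RETAINED", beta1=1.0, rho=1.0, gamma=-0.7)
    add_set("LOST", "SET_LOST", beta1=-1.0, rho=0.0, gamma=-0.7)
    add_set("INDUCED", "SET_INDUCED", beta1=0.0, beta1_cancer=1.0, gamma=2.0)
    add_set("FLAT", "SET_FLAT")
    for i in range(n_background):
        specs.append(GeneSpec(f"BG{i + 1:04d}", "BACKGROUND", beta0=draw_beta0()))
    return specs, GeneSetCollection(sets)


@dataclass(frozen=True)
class ScenarioSample:
    label: str
    condition: str
    counts: CountMatrix
    positions: PositionsTable
    layout: LobuleLayout


@dataclass(frozen=True)
class Scenario:
    samples: tuple[ScenarioSample, ...]
    gene_sets: GeneSetCollection
    specs: tuple[GeneSpec, ...]

    def truth_sets_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"set": name, "sham_sign": s, "cancer_sign": c}
                for name, (s, c) in TRUTH_SIGNS.items()
            ]
        )

    def truth_genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": s.gene_id,
                    "archetype": s.archetype,
                    "beta0": s.beta0,
                    "beta1": s.beta1,
                    "beta1_cancer": s.cancer_amplitude(),
                    "gamma": s.gamma,
                    "rho": s.rho,
                    "theta": s.theta,
                }
                for s in self.specs
            ]
        )


def default_scenario(
    seed: int,
    rows: int = 30,
    cols: int = 50,
    n_background: int = 2500,
    set_size: int = 25,
    n_portal: int = 4,
    n_central: int = 4,
) -> Scenario:
    """Two sham and two cancer samples with the programmed archetype sets."""
    specs, sets = default_gene_specs(seed, n_background=n_background, set_size=set_size)
    samples = []
    labels = [("sham_1", "sham"), ("sham_2", "sham"), ("cancer_1", "cancer"), ("cancer_2", "cancer")]
    for k, (label, condition) in enumerate(labels):
        sample_seed_root = np.random.SeedSequence(entropy=seed, spawn_key=(1 + k,))
        layout_seed, counts_seed = sample_seed_root.generate_state(2)
        layout = build_layout(rows, cols, 100.0, n_portal, n_central, int(layout_seed))
        cfg = SimConfig(rows=rows, cols=cols, condition=condition, seed=int(counts_seed))
        counts, positions = simulate_counts(layout, specs, cfg)
        samples.append(ScenarioSample(label, condition, counts, positions, layout))
    return Scenario(tuple(samples), sets, tuple(specs))


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, dict[str, str]]:
    """Emit the scenario as triplet bundles + positions + GMT + truth tables.

    Returns a manifest mapping sample labels to the written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    for sample in scenario.samples:
        d = outdir / sample.label
        d.mkdir(exist_ok=True)
        paths = {
            "matrix": str(d / "matrix.mtx"),
            "features": str(d / "features.tsv"),
            "barcodes": str(d / "barcodes.tsv"),
            "positions": str(d / "tissue_positions.csv"),
            "condition": sample.condition,
        }
        write_counts_triplet(
            sample.counts, paths["matrix"], paths["features"], paths["barcodes"]
        )
        write_tissue_positions(sample.positions, paths["positions"])
        manifest[sample.label] = paths
    write_gmt(scenario.gene_sets, outdir / "gene_sets.gmt")
    write_table(scenario.truth_sets_frame(), outdir / "truth_sets.tsv")
    write_table(scenario.truth_genes_frame(), outdir / "truth_genes.tsv", sort_by=None)
    return manifest
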