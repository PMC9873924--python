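"""End-to-end orchestration: simulate -> QC/normalise -> score -> zones -> tables.

Every stage is a plain function over a :class:`PipelineConfig`; the CLI
subcommands and :func:`run_all` call the same functions, so staged and
monolithic runs produce byte-identical outputs.  All randomness flows from
one top-level seed expanded into named sub-seeds recorded in the manifest.

Defaults reproduce the published analysis parameters: 24 expression bins and
100 control genes per set gene for module scores, equal tertile zones, top
10% landmark spots for the ring profiles, and 200 top-range sets for the
heatmap selection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .geometry import build_geometry
from .scoring import (
    filter_gene_sets,
    log_normalize,
    mito_spot_filter,
    module_score_matrix,
)
from .simulate import default_scenario, write_scenario
from .zonation import (
    ZoneConfig,
    assign_tertiles,
    normalize_profile_rows,
    ring_membership,
    select_top_range,
    zonation_profile,
    zone_volcano,
)

log = logging.getLogger("hepazone")

__version__ = "0.1.0"

#: registry of named sub-seed slots expanded from the top-level seed
_SEED_SLOTS = {"simulate": 0, "scoring": 1}


def derive_seed(seed: int, slot: str, index: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_SEED_SLOTS[slot], index))
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class SampleEntry:
    """One input sample: triplet bundle paths plus its condition label."""

    label: str
    condition: str
    matrix: str
    features: str
    barcodes: str
    positions: str


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "hepazone_out"
    seed: int = 0
    samples: tuple[SampleEntry, ...] = ()
    simulate: Mapping[str, Any] | None = None  # rows/cols/... for default_scenario
    gene_sets: str | None = None  # GMT path; simulated scenarios supply their own
    nbin: int = 24
    nctrl: int = 100
    min_set_size: int = 20
    max_set_size: int = 250
    portal_marker: str = "Alb"
    central_marker: str = "Cyp2e1"
    top_fraction: float = 0.10
    k_top: int = 200
    normalization: str = "zscore"
    mito_prefix: str = "mt-"
    mito_top_fraction: float = 0.10
    pitch_um: float = 100.0

    def zone_config(self) -> ZoneConfig:
        return ZoneConfig(self.portal_marker, self.central_marker, self.top_fraction)


def load_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Load a YAML config file; keyword overrides take precedence."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    samples = tuple(SampleEntry(**s) for s in raw.pop("samples", []))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(samples=samples, **raw)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> PipelineConfig:
    """Generate the default two-condition scenario and register its bundles."""
    if config.simulate is None:
        return config
    sim_kw = dict(config.simulate)
    sim_dir = Path(config.outdir) / "sim"
    seed = derive_seed(config.seed, "simulate")
    log.info("simulating default scenario: seed=%d options=%s", seed, sim_kw)
    scenario = default_scenario(seed, **sim_kw)
    manifest = write_scenario(scenario, sim_dir)
    samples = tuple(
        SampleEntry(
            label=label,
            condition=paths["condition"],
            matrix=paths["matrix"],
            features=paths["features"],
            barcodes=paths["barcodes"],
            positions=paths["positions"],
        )
        for label, paths in manifest.items()
    )
    return dataclasses.replace(
        config,
        samples=samples,
        simulate=None,
        gene_sets=str(sim_dir / "gene_sets.gmt"),
    )


def _load_sample(entry: SampleEntry, config: PipelineConfig):
    counts = hio.read_counts_triplet(entry.matrix, entry.features, entry.barcodes)
    positions = hio.read_tissue_positions(entry.positions)
    retained = mito_spot_filter(
        counts, config.mito_prefix, config.mito_top_fraction
    )
    if len(retained) < counts.n_spots:
        log.info(
            "%s: mito filter removed %d/%d spots",
            entry.label,
            counts.n_spots - len(retained),
            counts.n_spots,
        )
        counts = counts.subset_spots(retained)
    return counts, positions


def stage_score(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Per-sample module scores; writes ``scores_<label>.tsv``."""
    if not config.samples:
        raise ValueError("no samples configured")
    if config.gene_sets is None:
        raise ValueError("no gene_sets GMT configured")
    if not Path(config.gene_sets).exists():
        raise FileNotFoundError(f"gene sets file not found: {config.gene_sets}")
    sets = hio.read_gmt(config.gene_sets)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_scores: dict[str, pd.DataFrame] = {}
    for k, entry in enumerate(config.samples):
        counts, _ = _load_sample(entry, config)
        norm = log_normalize(counts)
        usable = filter_gene_sets(
            sets, norm.gene_ids, config.min_set_size, config.max_set_size
        )
        if not len(usable):
            raise ValueError(f"{entry.label}: no gene set survives the size filter")
        seed = derive_seed(config.seed, "scoring", k)
        log.info(
            "%s: scoring %d sets (nbin=%d nctrl=%d seed=%d)",
            entry.label, len(usable), config.nbin, config.nctrl, seed,
        )
        scores = module_score_matrix(
            norm, usable, nbin=config.nbin, nctrl=config.nctrl, seed=seed
        )
        all_scores[entry.label] = scores
        out = scores.reset_index(names="spot")
        hio.write_table(out, outdir / f"scores_{entry.label}.tsv", sort_by="spot")
    return all_scores


def _read_scores(config: PipelineConfig, label: str) -> pd.DataFrame:
    path = Path(config.outdir) / f"scores_{label}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing stage output {path}; run the score stage first")
    df = hio.read_table(path)
    if "spot" not in df.columns:
        raise ValueError(f"{path}: expected a 'spot' column")
    return df.set_index("spot")


def stage_zones(
    config: PipelineConfig, scores: Mapping[str, pd.DataFrame] | None = None
) -> dict[str, pd.DataFrame]:
    """Tertile zones and volcano tables, per sample and pooled per condition."""
    outdir = Path(config.outdir)
    zone_cfg = config.zone_config()
    per_sample_rows = []
    pooled: dict[str, list[tuple[pd.DataFrame, pd.Series]]] = {}
    for entry in config.samples:
        counts, _ = _load_sample(entry, config)
        norm = log_normalize(counts)
        s = scores[entry.label] if scores else _read_scores(config, entry.label)
        s = s.loc[list(norm.spot_ids)]
        labels = assign_tertiles(norm, zone_cfg)
        volcano = zone_volcano(s, labels)
        volcano.insert(0, "sample", entry.label)
        per_sample_rows.append(volcano)
        pooled.setdefault(entry.condition, []).append((s, labels))
    per_sample = pd.concat(per_sample_rows, ignore_index=True)
    hio.write_table(per_sample, outdir / "volcano_samples.tsv", sort_by=["sample", "set"])
    joint_rows = []
    for condition, parts in pooled.items():
        # tertiles are assigned per image, then spots pooled within condition
        s_all = pd.concat(
            [s.set_axis([f"{i}:{x}" for x in s.index]) for i, (s, _) in enumerate(parts)]
        )
        l_all = pd.concat(
            [l.set_axis([f"{i}:{x}" for x in l.index]) for i, (_, l) in enumerate(parts)]
        )
        volcano = zone_volcano(s_all, l_all)
        volcano.insert(0, "condition", condition)
        joint_rows.append(volcano)
    joint = pd.concat(joint_rows, ignore_index=True)
    hio.write_table(joint, outdir / "volcano_joint.tsv", sort_by=["condition", "set"])
    return {"volcano_samples": per_sample, "volcano_joint": joint}


def stage_profile(
    config: PipelineConfig, scores: Mapping[str, pd.DataFrame] | None = None
) -> dict[str, pd.DataFrame]:
    """Neighbour-ring zonation profiles, top-range selection and normalisation."""
    outdir = Path(config.outdir)
    zone_cfg = config.zone_config()
    profile_rows = []
    for entry in config.samples:
        counts, positions = _load_sample(entry, config)
        norm = log_normalize(counts)
        s = scores[entry.label] if scores else _read_scores(config, entry.label)
        s = s.loc[list(norm.spot_ids)]
        geometry = build_geometry(positions, config.pitch_um)
        membership = ring_membership(norm, geometry, zone_cfg)
        profile_rows.append(zonation_profile(s, membership, entry.label))
    profiles = pd.concat(profile_rows, ignore_index=True)
    # the top-range list is shared across all samples/conditions
    selected = select_top_range(profiles, k=config.k_top)
    normalized = normalize_profile_rows(profiles, mode=config.normalization)
    hio.write_table(profiles, outdir / "profiles.tsv", sort_by=["set", "sample", "class"])
    hio.write_table(
        normalized, outdir / "profiles_normalized.tsv", sort_by=["set", "sample", "class"]
    )
    hio.write_table(
        pd.DataFrame({"set": selected, "rank": range(1, len(selected) + 1)}),
        outdir / "selected_sets.tsv",
        sort_by="rank",
    )
    return {"profiles": profiles, "profiles_normalized": normalized}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every stage and write a manifest; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    config = stage_simulate(config)
    stage_score(config)
    # downstream stages re-read the written score tables so staged and
    # monolithic runs are byte-identical
    stage_zones(config)
    stage_profile(config)
    outputs = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "sub_seeds": {
            "simulate": derive_seed(config.seed, "simulate"),
            "scoring": [
                derive_seed(config.seed, "scoring", k)
                for k in range(len(config.samples))
            ],
        },
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "samples"
        },
        "samples": [dataclasses.asdict(s) for s in config.samples],
        "checksums": {name: _sha256(outdir / name) for name in outputs},
        "started": started,
        "finished": time.time(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished: %d outputs in %s", len(outputs), outdir)
    return outdir
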