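"""nCounter-like synthetic study generator with recorded ground truth.

The generator emulates the design of a kidney-biopsy immune-panel study:
511 endogenous probes, a 6-probe positive-control titration ladder, 6
negative-control background probes; four normal-control biopsies and three
lupus-nephritis response groups (complete, partial and non-responders, default
sizes 5/10/4); the LN assays split across two batches (9 + 10 lanes) with the
control samples assayed in both batches so they can anchor batch correction.

Count model
-----------
Endogenous probe g in assay a (sample s, batch b) is negative binomial with

    mean = lane_a * 2 ** (baseline_g + effect_{g, group(s)} + offset_{g, b})

and gene-level dispersion ``config.dispersion`` (Poisson at dispersion 0).
Negative probes are Poisson(background_mean * lane_a); positive probes follow
the titration ladder scaled by a calibration constant, with a small technical
dispersion. Lane factors are log-normal and fold in FFPE capture efficiency;
no separate per-patient biological random effect is modelled.

Randomness comes from a single ``numpy.random.default_rng(seed)`` stream,
drawn in a fixed, documented order (baselines, batch offsets, lane factors,
then the count blocks), so a seed pins every emitted number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CountMatrix, GROUPS, SampleTable, write_counts, write_meta

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedStudy",
    "default_de_spec",
    "simulate_study",
    "null_study",
    "write_fixture",
]


class ConfigError(ValueError):
    """A SimConfig field violates its invariant."""


# Fold changes printed for the group-unique signature genes in the source
# study's differential-expression table; the shared 19-gene core (12 up, 7
# down) is planted at +/-2 log2.
_CR_UNIQUE_FOLDS = (2.17, 2.16, 0.48)
_NR_UNIQUE_FOLDS = (
    2.23, 2.23, 2.21, 2.17, 2.11, 2.07, 2.01, 2.01,
    0.49, 0.49, 0.49, 0.47, 0.47, 0.46, 0.46, 0.46, 0.46, 0.45, 0.44, 0.41,
)
_PR_UNIQUE_FOLDS = (2.2, 0.46, 0.46, 0.44, 0.41, 0.41, 0.11)
CORE_SIZE = 19
_CORE_UP = 12


def default_de_spec() -> dict[str, list[tuple[int, float]]]:
    """Planted signatures mirroring the study's Venn structure.

    A 19-gene core shared by all three LN response groups (genes 0-18, twelve
    up at +2 log2 and seven down at -2), then 3 CR-unique, 20 NR-unique and 7
    PR-unique genes whose effects are the log2 of published fold changes.
    """
    core = [(g, 2.0 if g < _CORE_UP else -2.0) for g in range(CORE_SIZE)]
    spec: dict[str, list[tuple[int, float]]] = {"CR": [], "PR": [], "NR": []}
    idx = CORE_SIZE
    for group, folds in (("CR", _CR_UNIQUE_FOLDS),
                         ("NR", _NR_UNIQUE_FOLDS),
                         ("PR", _PR_UNIQUE_FOLDS)):
        spec[group] = list(core)
        for fold in folds:
            spec[group].append((idx, float(np.log2(fold))))
            idx += 1
    return spec


@dataclass
class SimConfig:
    """Generator parameters; defaults reproduce the emulated study design."""

    n_endogenous: int = 511
    n_pos: int = 6
    n_neg: int = 6
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "CR": 5, "PR": 10, "NR": 4})
    #: how the non-control samples split across assay batches, in sample order
    batch_sizes: tuple[int, ...] = (9, 10)
    #: explicit sample -> batch map for non-control samples (overrides batch_sizes)
    batch_assignment: dict[str, str] | None = None
    #: True: controls independently re-assayed in every batch;
    #: False: a single control assay is reused (duplicated) across batches
    replicate_controls: bool = True
    baseline_log2_mean_range: tuple[float, float] = (6.0, 12.0)
    dispersion: float = 0.03
    lane_factor_sd: float = 0.15
    batch_offset_sd: float = 0.5
    background_mean: float = 10.0
    pos_ladder: tuple[float, ...] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    pos_calibration: float = 200.0
    pos_dispersion: float = 0.005
    #: endogenous genes simulated at background level (not expressed); the
    #: last ``n_background_genes`` indices — default leaves 400 expressed
    n_background_genes: int = 111
    de_spec: dict[str, list[tuple[int, float]]] = field(
        default_factory=default_de_spec)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_endogenous", "n_pos", "n_neg"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not self.group_sizes:
            raise ConfigError("group_sizes is empty")
        bad = set(self.group_sizes) - set(GROUPS)
        if bad:
            raise ConfigError(f"group_sizes: unknown group label(s) {sorted(bad)}")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ConfigError("group_sizes: all sizes must be strictly positive")
        if "control" not in self.group_sizes:
            raise ConfigError("group_sizes must include 'control'")
        n_ln = sum(n for g, n in self.group_sizes.items() if g != "control")
        if n_ln == 0:
            raise ConfigError("group_sizes must include at least one LN group")
        if self.batch_assignment is None and sum(self.batch_sizes) != n_ln:
            raise ConfigError(
                f"batch_sizes sum to {sum(self.batch_sizes)} but there are "
                f"{n_ln} non-control samples")
        ladder = np.asarray(self.pos_ladder, dtype=float)
        if len(ladder) != self.n_pos:
            raise ConfigError("pos_ladder length must equal n_pos")
        if (ladder <= 0).any() or (np.diff(ladder) >= 0).any():
            raise ConfigError("pos_ladder must be strictly decreasing and positive")
        if self.dispersion < 0 or self.pos_dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.lane_factor_sd < 0 or self.batch_offset_sd < 0:
            raise ConfigError("lane_factor_sd/batch_offset_sd must be non-negative")
        if self.background_mean <= 0:
            raise ConfigError("background_mean must be strictly positive")
        if not 0 <= self.n_background_genes < self.n_endogenous:
            raise ConfigError("n_background_genes must be in [0, n_endogenous)")
        lo, hi = self.baseline_log2_mean_range
        if not lo < hi:
            raise ConfigError("baseline_log2_mean_range must be increasing")
        n_expressed = self.n_endogenous - self.n_background_genes
        for group, entries in self.de_spec.items():
            if group not in GROUPS or group == "control":
                raise ConfigError(f"de_spec: invalid group {group!r}")
            idx = [g for g, _ in entries]
            if len(idx) != len(set(idx)):
                raise ConfigError(f"de_spec[{group}]: duplicate gene indices")
            out = [g for g in idx if not 0 <= g < n_expressed]
            if out:
                raise ConfigError(
                    f"de_spec[{group}]: gene indices {out[:5]} outside the "
                    f"expressed endogenous range [0, {n_expressed})")

    # -- derived layout -----------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"GENE_{i + 1:03d}" for i in range(self.n_endogenous)]

    def probe_ids(self) -> tuple[list[str], list[str], list[str]]:
        pos = [f"POS_{chr(65 + i)}({c:g})" for i, c in enumerate(self.pos_ladder)]
        neg = [f"NEG_{chr(65 + i)}" for i in range(self.n_neg)]
        return self.gene_ids(), pos, neg

    def sample_ids(self) -> dict[str, list[str]]:
        order = [g for g in GROUPS if g in self.group_sizes]
        return {g: [f"{g.upper() if g != 'control' else 'CTRL'}{i + 1}"
                    for i in range(self.group_sizes[g])] for g in order}

    def batch_labels(self) -> list[str]:
        if self.batch_assignment is not None:
            return sorted(set(self.batch_assignment.values()))
        return [f"B{i + 1}" for i in range(len(self.batch_sizes))]

    def assignment(self) -> dict[str, str]:
        """Batch of every non-control sample."""
        samples = self.sample_ids()
        ln = [s for g, ss in samples.items() if g != "control" for s in ss]
        if self.batch_assignment is not None:
            missing = set(ln) - set(self.batch_assignment)
            if missing:
                raise ConfigError(
                    f"batch_assignment missing sample(s): {sorted(missing)[:5]}")
            return {s: self.batch_assignment[s] for s in ln}
        out: dict[str, str] = {}
        pos = 0
        for label, size in zip(self.batch_labels(), self.batch_sizes):
            for s in ln[pos:pos + size]:
                out[s] = label
            pos += size
        return out


@dataclass
class GroundTruth:
    """Every planted quantity, for parameter-recovery testing."""

    true_de: dict[str, list[tuple[str, float]]]
    lane_factors: pd.Series
    batch_offsets: pd.DataFrame  # genes x batches, reference batch all-zero
    expressed_mask: pd.Series  # bool per endogenous gene
    baseline_log2: pd.Series

    def effects_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "gene": gene, "log2_effect": eff}
            for g, entries in self.true_de.items()
            for gene, eff in entries
        ]
        return pd.DataFrame(rows, columns=["group", "gene", "log2_effect"])


@dataclass
class SimulatedStudy:
    counts: CountMatrix
    meta: SampleTable
    truth: GroundTruth
    config: SimConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterisation; Poisson at 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Draw one complete study (counts + metadata + ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids, pos_ids, neg_ids = config.probe_ids()
    n_expressed = config.n_endogenous - config.n_background_genes
    expressed_mask = pd.Series(
        [i < n_expressed for i in range(config.n_endogenous)], index=gene_ids)

    lo, hi = config.baseline_log2_mean_range
    baselines = pd.Series(rng.uniform(lo, hi, size=config.n_endogenous),
                          index=gene_ids)

    batches = config.batch_labels()
    ref_batch = batches[0]
    offsets = pd.DataFrame(0.0, index=gene_ids, columns=batches)
    for b in batches[1:]:
        offsets[b] = rng.normal(0.0, config.batch_offset_sd,
                                size=config.n_endogenous)

    # assay layout: controls first (once per batch if replicated), then LN
    samples = config.sample_ids()
    assignment = config.assignment()
    layout: list[tuple[str, str, str, str]] = []  # assay, sample, group, batch
    for s in samples.get("control", []):
        for b in batches:
            layout.append((f"{s}_{b}", s, "control", b))
    for g in ("CR", "PR", "NR"):
        for s in samples.get(g, []):
            b = assignment[s]
            layout.append((f"{s}_{b}", s, g, b))

    meta = SampleTable(pd.DataFrame(
        layout, columns=["assay_id", "sample_id", "group", "batch"]))
    assay_ids = meta.assay_ids

    # lane factors: one physical lane per assay; if control data are reused
    # rather than re-assayed, both batch entries share one physical lane
    physical: dict[str, str] = {}  # assay -> physical lane key
    for assay, s, g, b in layout:
        if g == "control" and not config.replicate_controls:
            physical[assay] = s
        else:
            physical[assay] = assay
    lane_keys = list(dict.fromkeys(physical.values()))
    lane_draw = dict(zip(
        lane_keys,
        np.exp(rng.normal(0.0, config.lane_factor_sd, size=len(lane_keys)))))
    lane_factors = pd.Series({a: lane_draw[physical[a]] for a in assay_ids},
                             index=assay_ids)

    # per-assay endogenous means
    effects = np.zeros((config.n_endogenous, len(assay_ids)))
    gene_effect_by_group: dict[str, np.ndarray] = {}
    for g, entries in config.de_spec.items():
        vec = np.zeros(config.n_endogenous)
        for idx, eff in entries:
            vec[idx] = eff
        gene_effect_by_group[g] = vec
    for j, (assay, s, g, b) in enumerate(layout):
        effects[:, j] = gene_effect_by_group.get(g, 0.0)

    batch_of = np.array([b for _, _, _, b in layout])
    off = offsets[batch_of].to_numpy()
    lane = lane_factors.to_numpy()[None, :]
    log2_mean = baselines.to_numpy()[:, None] + effects + off
    mean_expressed = lane * np.exp2(log2_mean)
    mean_expressed[~expressed_mask.to_numpy(), :] = (
        config.background_mean * lane)

    # count draws (documented order: endogenous block, positive, negative);
    # reused control lanes share one column of draws
    col_of_key = {}
    for key in lane_keys:
        # representative assay for this physical lane
        rep = next(a for a in assay_ids if physical[a] == key)
        col_of_key[key] = assay_ids.index(rep)
    endo_unique = np.empty((config.n_endogenous, len(lane_keys)), dtype=np.int64)
    for k, key in enumerate(lane_keys):
        mu = mean_expressed[:, col_of_key[key]]
        expressed = expressed_mask.to_numpy()
        col = np.empty(config.n_endogenous, dtype=np.int64)
        col[expressed] = _nb_draw(rng, mu[expressed], config.dispersion)
        col[~expressed] = rng.poisson(mu[~expressed])
        endo_unique[:, k] = col
    ladder = np.asarray(config.pos_ladder, dtype=float)
    pos_unique = np.empty((config.n_pos, len(lane_keys)), dtype=np.int64)
    neg_unique = np.empty((config.n_neg, len(lane_keys)), dtype=np.int64)
    for k, key in enumerate(lane_keys):
        lane_k = lane_draw[key]
        pos_unique[:, k] = _nb_draw(
            rng, ladder * config.pos_calibration * lane_k, config.pos_dispersion)
        neg_unique[:, k] = rng.poisson(
            np.full(config.n_neg, config.background_mean * lane_k))
    key_index = {key: k for k, key in enumerate(lane_keys)}
    cols = [key_index[physical[a]] for a in assay_ids]
    values = np.vstack([endo_unique, pos_unique, neg_unique])[:, cols]

    probe_ids = gene_ids + pos_ids + neg_ids
    probe_class = pd.Series(
        ["Endogenous"] * config.n_endogenous + ["Positive"] * config.n_pos
        + ["Negative"] * config.n_neg, index=probe_ids, name="probe_class")
    counts = CountMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=assay_ids),
        probe_class=probe_class)

    true_de = {
        g: [(gene_ids[idx], float(eff)) for idx, eff in entries]
        for g, entries in config.de_spec.items()
    }
    truth = GroundTruth(
        true_de=true_de,
        lane_factors=lane_factors,
        batch_offsets=offsets,
        expressed_mask=expressed_mask,
        baseline_log2=baselines,
    )
    return SimulatedStudy(counts=counts, meta=meta, truth=truth, config=config)


def null_study(config: SimConfig) -> SimulatedStudy:
    """As :func:`simulate_study` but with every planted effect removed."""
    return simulate_study(dataclasses.replace(config, de_spec={}))


def two_group_null_config(n_genes: int = 400, n_control: int = 4,
                          n_case: int = 5, seed: int = 0) -> SimConfig:
    """Config for a two-group null study used in type-I-error calibration.

    All genes expressed, one assay batch, no planted effects: every
    case-vs-control difference is pure noise, so the count of genes passing
    a threshold alpha estimates m * alpha false positives.
    """
    return SimConfig(
        n_endogenous=n_genes, n_background_genes=0,
        group_sizes={"control": n_control, "CR": n_case},
        batch_sizes=(n_case,), de_spec={}, seed=seed)


def write_fixture(study: SimulatedStudy, directory: str | Path) -> dict[str, Path]:
    """Persist a study as TSVs + a YAML config; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "counts": directory / "counts.tsv",
        "meta": directory / "meta.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.yaml",
    }
    write_counts(study.counts, manifest["counts"])
    write_meta(study.meta, manifest["meta"])
    study.truth.effects_frame().to_csv(manifest["truth"], sep="\t", index=False)
    cfg = dataclasses.asdict(study.config)
    cfg["de_spec"] = {g: [[int(i), float(e)] for i, e in entries]
                      for g, entries in cfg["de_spec"].items()}
    cfg["pos_ladder"] = list(cfg["pos_ladder"])
    cfg["batch_sizes"] = list(cfg["batch_sizes"])
    cfg["baseline_log2_mean_range"] = list(cfg["baseline_log2_mean_range"])
    manifest["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return manifest


def config_from_yaml(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    kwargs = dict(raw)
    if "de_spec" in kwargs and kwargs["de_spec"] is not None:
        kwargs["de_spec"] = {g: [(int(i), float(e)) for i, e in entries]
                             for g, entries in kwargs["de_spec"].items()}
    for key in ("pos_ladder", "batch_sizes", "baseline_log2_mean_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(SimConfig)}
    if unknown:
        raise ConfigError(f"unknown SimConfig field(s): {sorted(unknown)}")
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg
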