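"""Seed-reproducible multiblock LC-MS peak-table simulator with known effects.

The generator emulates the structure of a designed tobacco suspension-culture
screen profiled by three analytical blocks (RP/ESI+, RP/ESI- and HILIC/ESI+):
log-normal feature intensities, factor-driven up/down regulation of designated
feature sets on the log scale, hormone-derivative features present only when
the hormone is supplied, partial feature sharing across blocks, blank runs,
pure-additive runs and pooled QC injections. Every injected effect is emitted
alongside the data so downstream selection can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Design, indicator_matrix, read_design, write_design

__all__ = [
    "EffectSpec",
    "SimConfig",
    "MultiBlockDataset",
    "simulate_dataset",
    "tobacco_screen_config",
    "METABOLITE_NAMES",
]

#: identified-metabolite naming fixture for the simulated screen
METABOLITE_NAMES = [
    "pentosyl-hexosyl-geranidiol", "pentosyl-hexosyl-geraniol",
    "hexosyl-geraniol", "malonyl-hexosyl-geraniol", "hexosyl-geranidiol",
    "hexosyl-hexosyl-geraniol", "malonyl-hexosyl-geranidiol", "glutamine",
    "scopolin", "hydroxysphingosine", "adenosine", "scopoletin",
    "scopoletin derivative", "metabolite of 2,4-D (1)",
    "metabolite of 2,4-D (2)", "metabolite of 2,4-D (3)",
    "indole-3-carboxylic acid glucoside", "metabolite of NAA (1)",
    "metabolite of NAA (2)", "IBA glycoside", "glycoside of DHZ",
    "DHZ adduct", "DHZ metabolite", "kinetin glucoside", "kinetin riboside",
    "BAP glucoside", "BAP riboside", "BAP ribotide",
    "C16:3 monoacylglycerol", "salicylic acid glucoside",
    "salicylic acid, dihexosyl-glucoside", "cyclanilide metabolite (1)",
    "cyclanilide metabolite (2)", "cyclanilide metabolite (3)",
    "ABA glycoside", "ABA metabolite", "trihydroxy-C18:2 acid (1)",
    "trihydroxy-C18:2 acid (2)", "glycoside of abscisic acid metabolite",
    "unidentified fatty acid with conjugated triene (1)",
    "unidentified fatty acid with conjugated triene (2)",
    "unidentified fatty acid with conjugated triene (3)",
    "dihydroxy-C18:2 fatty acid (conjugated)", "potassium ion", "nicotine",
]

_DERIVATIVES = {
    "IAA": ["indole-3-carboxylic acid glucoside"],
    "IBA": ["IBA glycoside"],
    "NAA": ["metabolite of NAA (1)", "metabolite of NAA (2)"],
    "2,4-D": ["metabolite of 2,4-D (1)", "metabolite of 2,4-D (2)",
              "metabolite of 2,4-D (3)"],
    "kinetin": ["kinetin glucoside", "kinetin riboside"],
    "DHZ": ["glycoside of DHZ", "DHZ adduct", "DHZ metabolite"],
    "BAP": ["BAP glucoside", "BAP riboside", "BAP ribotide"],
}


class ConfigurationError(ValueError):
    """An effect or map refers to an unknown feature, factor or block."""


@dataclass(frozen=True)
class EffectSpec:
    """A known up/down regulation of a feature set under one indicator.

    ``magnitude`` is the log-intensity shift in units of the residual SD
    applied to runs where the indicator equals 1.
    """

    indicator: str
    feature_ids: tuple[str, ...]
    direction: str  # "up" | "down"
    magnitude: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "up" else -1.0


@dataclass
class SimConfig:
    """Full parameterisation of one simulated screen.

    Feature identifiers are *latent* ids; a latent feature shared across
    blocks materialises as one column per block (independent noise, small m/z
    jitter). ``noise_sd`` is the log-scale residual SD; effect magnitudes are
    expressed in units of it.
    """

    blocks: list[tuple[str, int]]
    shared_feature_fraction: float = 0.15
    effects: list[EffectSpec] = field(default_factory=list)
    derivative_features: dict[str, list[str]] = field(default_factory=dict)
    background_features: list[str] = field(default_factory=list)
    additive_features: dict[str, list[str]] = field(default_factory=dict)
    named_features: dict[str, list[str]] = field(default_factory=dict)
    noise_sd: float = 0.4
    baseline_loc: float = 8.0
    baseline_scale: float = 1.5
    noise_floor: float = 10.0
    n_blanks: int = 3
    n_qc: int = 9
    qc_cv_target: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not self.blocks or any(n <= 0 for _, n in self.blocks):
            raise ConfigurationError("every block needs n_features > 0")
        if not 0 <= self.shared_feature_fraction <= 1:
            raise ConfigurationError("shared_feature_fraction must be in [0,1]")
        if not 0 <= self.qc_cv_target <= 1:
            raise ConfigurationError("qc_cv_target must be in [0,1]")
        if self.noise_sd < 0 or self.noise_floor <= 0:
            raise ConfigurationError("noise_sd >= 0 and noise_floor > 0 required")


@dataclass
class MultiBlockDataset:
    """Aligned sample x feature intensity matrices for >= 1 analytical blocks.

    All blocks share the same sample index in the same order; intensities are
    non-negative (arbitrary units). ``features[block]`` carries feature_id,
    latent_id, m/z (Da) and retention time (min); ``sample_roles`` maps each
    sample to experiment/blank/qc/additive. ``ground_truth`` lists the
    injected effects (simulated data only).
    """

    blocks: dict[str, pd.DataFrame]
    features: dict[str, pd.DataFrame]
    sample_roles: pd.Series
    design: Design | None = None
    ground_truth: list[EffectSpec] = field(default_factory=list)
    metabolite_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.sample_roles.index[self.sample_roles == role])

    def experiment_matrix(self, block: str) -> pd.DataFrame:
        return self.blocks[block].loc[self.samples_with_role("experiment")]

    def truth_latents(self, indicator: str) -> set[str]:
        return {
            fid for e in self.ground_truth if e.indicator == indicator
            for fid in e.feature_ids
        }

    # -- I/O ---------------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.blocks.items():
            df.to_csv(outdir / f"{name}.csv")
            self.features[name].to_csv(outdir / f"{name}.features.csv", index=False)
        self.sample_roles.rename("role").to_csv(outdir / "samples.csv")
        meta = {
            "ground_truth": [
                {"indicator": e.indicator, "feature_ids": list(e.feature_ids),
                 "direction": e.direction, "magnitude": e.magnitude}
                for e in self.ground_truth
            ],
            "metabolite_map": self.metabolite_map,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1))
        if self.design is not None:
            write_design(self.design, outdir / "design.csv")

    @classmethod
    def read(cls, outdir: str | Path) -> "MultiBlockDataset":
        outdir = Path(outdir)
        roles = pd.read_csv(outdir / "samples.csv", index_col=0)["role"]
        blocks, features = {}, {}
        for fpath in sorted(outdir.glob("*.features.csv")):
            name = fpath.name.removesuffix(".features.csv")
            features[name] = pd.read_csv(fpath)
            blocks[name] = pd.read_csv(outdir / f"{name}.csv", index_col=0)
        meta = {}
        gt_path = outdir / "ground_truth.json"
        if gt_path.exists():
            meta = json.loads(gt_path.read_text())
        truth = [
            EffectSpec(d["indicator"], tuple(d["feature_ids"]), d["direction"],
                       d["magnitude"])
            for d in meta.get("ground_truth", [])
        ]
        design = None
        if (outdir / "design.csv").exists():
            design = read_design(outdir / "design.csv")
        return cls(blocks=blocks, features=features, sample_roles=roles,
                   design=design, ground_truth=truth,
                   metabolite_map=meta.get("metabolite_map", {}))


# ---------------------------------------------------------------------------

def _latent_layout(config: SimConfig) -> tuple[dict[str, list[str]], list[str]]:
    """Assign latent feature ids to blocks; shared ones appear in all blocks.

    Named latents (metabolite fixtures, backgrounds, additives, derivatives)
    are placed first, cycling over blocks; the remainder are anonymous
    block-local latents, the leading fraction of which is shared.
    """
    named = sorted(
        set(config.background_features)
        | {f for v in config.additive_features.values() for f in v}
        | {f for v in config.derivative_features.values() for f in v}
        | {f for v in config.named_features.values() for f in v}
    )
    block_names = [b for b, _ in config.blocks]
    per_block: dict[str, list[str]] = {b: [] for b in block_names}
    for i, latent in enumerate(named):
        per_block[block_names[i % len(block_names)]].append(latent)
    all_latents = list(named)
    for b, n_feat in config.blocks:
        n_shared = int(round(config.shared_feature_fraction * n_feat))
        room = n_feat - len(per_block[b])
        if room < 0:
            raise ConfigurationError(
                f"block {b}: n_features={n_feat} smaller than its named features"
            )
        if b != block_names[0]:
            take = min(n_shared, room, len(per_block[block_names[0]]))
            shared = [
                lt for lt in per_block[block_names[0]][:take]
            ]
            per_block[b].extend(shared)
            room -= take
        fresh = [f"{b}_L{i:05d}" for i in range(room)]
        per_block[b].extend(fresh)
        all_latents.extend(fresh)
    return per_block, all_latents


def simulate_dataset(design: Design, config: SimConfig) -> MultiBlockDataset:
    """Draw one multiblock dataset with the configured ground-truth effects.

    Log intensity of latent l in experiment run s is
    ``baseline_l + sum(sign * magnitude * noise_sd * indicator_s) + N(0, noise_sd)``;
    intensities are ``exp`` of that, hence non-negative. Derivative features
    sit at the noise floor when their hormone is absent; blanks contain only
    background features; additive runs only that additive's features; QC
    injections are noisy copies of the pooled experiment mean with
    log-scale dispersion matched to ``qc_cv_target``. Identical
    (design, config) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ind = indicator_matrix(design)
    known = set(ind.columns)
    per_block, all_latents = _latent_layout(config)
    latent_set = set(all_latents)
    for e in config.effects:
        if e.indicator not in known:
            raise ConfigurationError(f"effect references unknown indicator {e.indicator!r}")
        missing = set(e.feature_ids) - latent_set
        if missing:
            raise ConfigurationError(f"effect references unknown features {sorted(missing)}")
    for horm, feats in config.derivative_features.items():
        if horm not in known:
            raise ConfigurationError(f"derivative map references unknown hormone {horm!r}")
        if set(feats) - latent_set:
            raise ConfigurationError(f"derivative features of {horm!r} not in layout")

    baseline = {
        lt: rng.normal(config.baseline_loc, config.baseline_scale)
        for lt in all_latents
    }
    shift = {lt: np.zeros(design.runs) for lt in all_latents}
    for e in config.effects:
        delta = e.sign * e.magnitude * config.noise_sd * ind[e.indicator].to_numpy()
        for lt in e.feature_ids:
            shift[lt] = shift[lt] + delta
    floor_log = float(np.log(config.noise_floor))
    floor_jit = 0.5 * config.noise_sd  # keeps absent features noisy but sub-threshold
    derivative_of = {
        lt: horm for horm, feats in config.derivative_features.items() for lt in feats
    }
    background = set(config.background_features)
    additive_of: dict[str, str] = {}
    for add, feats in config.additive_features.items():
        for lt in feats:
            additive_of[lt] = add

    exp_ids = [f"run_{i:03d}" for i in design.assignment.index]
    blank_ids = [f"blank_{i + 1}" for i in range(config.n_blanks)]
    add_ids = [f"additive_{a}" for a in config.additive_features]
    qc_ids = [f"qc_{i + 1}" for i in range(config.n_qc)]
    samples = exp_ids + blank_ids + add_ids + qc_ids
    roles = pd.Series(
        ["experiment"] * len(exp_ids) + ["blank"] * len(blank_ids)
        + ["additive"] * len(add_ids) + ["qc"] * len(qc_ids),
        index=pd.Index(samples, name="sample_id"),
    )
    qc_sigma = float(np.sqrt(np.log1p(config.qc_cv_target**2)))

    blocks: dict[str, pd.DataFrame] = {}
    features: dict[str, pd.DataFrame] = {}
    n_runs = design.runs
    for b, n_feat in config.blocks:
        latents = per_block[b]
        fids = [f"{b}_F{i:04d}" for i in range(len(latents))]
        mz = rng.uniform(100.0, 1200.0, len(latents))
        rt = rng.uniform(1.6, 24.6, len(latents))
        log_exp = np.empty((n_runs, len(latents)))
        for j, lt in enumerate(latents):
            mu = baseline[lt] + shift[lt]
            if lt in derivative_of:
                present = ind[derivative_of[lt]].to_numpy().astype(bool)
                vals = np.where(
                    present,
                    mu + rng.normal(0, config.noise_sd, n_runs),
                    floor_log + rng.normal(0, floor_jit, n_runs),
                )
            else:
                vals = mu + rng.normal(0, config.noise_sd, n_runs)
            log_exp[:, j] = vals
        X_exp = np.exp(log_exp)

        # blanks: background features only, everything else at the noise floor
        is_bg = np.array([lt in background for lt in latents])
        log_blank = np.where(
            is_bg[None, :],
            np.array([baseline[lt] for lt in latents])[None, :]
            + rng.normal(0, config.noise_sd, (config.n_blanks, len(latents))),
            floor_log + rng.normal(0, floor_jit, (config.n_blanks, len(latents))),
        )
        # additive runs: only that additive's designated features are present
        rows_add = []
        for add in config.additive_features:
            is_add = np.array([additive_of.get(lt) == add for lt in latents])
            row = np.where(
                is_add,
                np.array([baseline[lt] for lt in latents])
                + rng.normal(0, config.noise_sd, len(latents)),
                floor_log + rng.normal(0, floor_jit, len(latents)),
            )
            rows_add.append(row)
        X_add = np.exp(np.vstack(rows_add)) if rows_add else np.empty((0, len(latents)))
        pooled = X_exp.mean(axis=0)
        X_qc = pooled[None, :] * np.exp(
            rng.normal(0, qc_sigma, (config.n_qc, len(latents)))
        )
        X = np.vstack([X_exp, np.exp(log_blank), X_add, X_qc])
        blocks[b] = pd.DataFrame(X, index=pd.Index(samples, name="sample_id"),
                                 columns=fids)
        features[b] = pd.DataFrame({
            "feature_id": fids,
            "latent_id": latents,
            "mz": np.round(mz, 4),
            "rt": np.round(rt, 4),
            "block": b,
        })
    return MultiBlockDataset(
        blocks=blocks, features=features, sample_roles=roles, design=design,
        ground_truth=list(config.effects),
        metabolite_map={k: v for k, v in config.named_features.items()
                        if not k.startswith("_")},
    )


def tobacco_screen_config(seed: int, n_features: tuple[int, int, int] = (1500, 1366, 1368)
                          ) -> SimConfig:
    """Simulation config mirroring the qualitative structure of the screen.

    Strong effects (magnitude 2.5 SD on ~18 features) for the macronutrients
    KNO3/NH4NO3/CaCl2, the elicitors MeJA/salicylic acid/cyclanilide/ABA and
    light; weak effects (0.9 SD on 8 features) for GA3 and ethephon; no
    effects at all for KH2PO4 and MgSO4 (the null factors of the screen).
    Each hormone carries derivative features that exist only in its runs plus
    an up-regulated response set. 45 named metabolite fixtures are distributed
    over the three blocks; their ion features double as the effect carriers
    where a natural assignment exists (hormone derivatives, geraniol
    glycosides responding to nutrients).

    ``n_features`` shrinks the blocks for reduced-cost runs (e.g. (200, 180,
    180)) without changing the effect structure.
    """
    blocks = [("RPPOS", n_features[0]), ("RPNEG", n_features[1]),
              ("HILIC", n_features[2])]

    named: dict[str, list[str]] = {}
    for i, met in enumerate(METABOLITE_NAMES):
        n_ions = 1 + (i % 3)  # 1-3 characteristic ions per metabolite
        named[met] = [f"M{i + 1:02d}_ion{j + 1}" for j in range(n_ions)]

    derivative_features = {
        horm: [fid for met in mets for fid in named[met]]
        for horm, mets in _DERIVATIVES.items()
    }
    background = [f"BG_{i:03d}" for i in range(30)]
    additive_features = {
        horm: [f"ADD_{horm}_{i}" for i in range(2)] for horm in _DERIVATIVES
    }

    strong = ["KNO3", "NH4NO3", "CaCl2", "MeJA", "salicylic_acid",
              "cyclanilide", "ABA", "light"]
    weak = ["GA3", "ethephon"]
    effects: list[EffectSpec] = []
    # geraniol-related glycosides respond coherently to KNO3 (co-regulated set)
    geraniol = [fid for met in METABOLITE_NAMES[:7] for fid in named[met]]
    effects.append(EffectSpec("KNO3", tuple(geraniol), "up", 2.5))
    for fac in strong:
        ups = tuple(f"RESP_{fac}_u{i}" for i in range(12))
        downs = tuple(f"RESP_{fac}_d{i}" for i in range(6))
        effects.append(EffectSpec(fac, ups, "up", 2.5))
        effects.append(EffectSpec(fac, downs, "down", 2.5))
    for fac in weak:
        ups = tuple(f"RESP_{fac}_u{i}" for i in range(10))
        effects.append(EffectSpec(fac, ups, "up", 1.5))
    for horm, feats in derivative_features.items():
        effects.append(EffectSpec(horm, tuple(feats), "up", 3.0))
        resp = tuple(f"RESP_{horm.replace(',', '')}_u{i}" for i in range(6))
        effects.append(EffectSpec(horm, resp, "up", 2.0))

    # every anonymous responsive latent must exist in the layout; stash them
    # under a non-metabolite key (leading underscore keys are layout-only)
    resp_latents = sorted({
        fid for e in effects for fid in e.feature_ids if fid.startswith("RESP_")
    })
    named_features = dict(named)
    named_features["_responsive"] = resp_latents

    return SimConfig(
        blocks=blocks,
        shared_feature_fraction=0.15,
        effects=effects,
        derivative_features=derivative_features,
        background_features=background,
        additive_features=additive_features,
        named_features=named_features,
        noise_sd=0.4,
        baseline_loc=8.0,
        baseline_scale=1.5,
        noise_floor=10.0,
        n_blanks=3,
        n_qc=9,
        qc_cv_target=0.15,
        seed=seed,
    )
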