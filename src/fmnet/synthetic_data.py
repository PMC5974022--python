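"""Synthetic coupled microbiome / metabolome / clinical cohorts.

Emulates a faecal case-control cohort (default 35 cirrhotic + 14 control
samples) with known ground truth so every downstream stage is testable
without access to raw sequencing deposits:

* a block-structured latent layer (per-block standard-normal factors, weakly
  coupled through a shared-environment component) gives planted functional
  communities whose members are strongly correlated;
* designated keystone features load equally on two block factors, making
  them the only bridges between communities after correlation thresholding;
* taxon counts are multinomial draws from softmax-transformed latents at
  realistic library sizes, on top of a large unstructured rare background
  that absorbs compositional closure;
* metabolite buckets are noisy linear images of the same latents, scaled by
  per-sample dilution factors (recoverable by PQN);
* a binary hepatic-encephalopathy label is drawn from a logistic model on
  chosen feature latents.

All randomness derives from one master seed, with an independent stream per
output block so adding outputs never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from fmnet._utils import child_seeds, write_table
from fmnet.abundance import AbundanceTable
from fmnet.nmr_preprocessing import NmrBucketMatrix, Spectrum


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


@dataclass
class SyntheticCohortSpec:
    """Parameters of the generated cohort.

    Defaults mirror the emulated study: 35 cases + 14 controls, ~63 merged
    features (50 taxa + 13 metabolites, the size of the faecal networks),
    library sizes from ~3101 reads upward, 2-fold dilution spread, and an HE
    base rate of 8/38 (logit intercept) among labelled subjects.
    """

    n_cases: int = 35
    n_controls: int = 14
    n_taxa: int = 50
    n_metabolites: int = 13
    n_blocks: int = 5
    block_corr: float = 0.90
    # weak shared-environment coupling between block factors; a bridge node
    # between two *independent* blocks can correlate at most 1/sqrt(2) with
    # either side, so without this coupling no keystone could clear a strict
    # |r| > 0.7 edge threshold even in the noise-free limit
    block_factor_corr: float = 0.50
    n_keystones: int = 2
    depth_range: tuple[int, int] = (3101, 30000)
    dilution_range: tuple[float, float] = (0.5, 2.0)
    he_beta: dict[str, float] = field(default_factory=dict)
    he_intercept: float = _logit(8 / 46)
    noise_sd: float = 0.10
    seed: int = 0
    latent_scale: float = 1.0   # taxon log-abundance response to its latent
    # Unstructured background community/buckets. The block-structured taxa are
    # a minority subcomposition (as the >=0.5% features are of a ~2000-OTU
    # community); without this the softmax closure forces strong spurious
    # anti-correlation between blocks and no threshold separates them.
    n_background_taxa: int = 150
    background_share: float = 0.65  # of total community mass, on average
    n_background_buckets: int = 30

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_taxa", "n_metabolites", "n_blocks"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 < self.block_corr < 1.0:
            raise ValueError("block_corr must lie strictly between 0 and 1")
        if not 0.0 <= self.block_factor_corr < 1.0:
            raise ValueError("block_factor_corr must lie in [0, 1)")
        if self.n_keystones < 0 or self.n_keystones > self.n_metabolites:
            raise ValueError("n_keystones must be between 0 and n_metabolites")
        if self.n_keystones > 0 and self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2 to plant keystone bridges")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be an increasing positive pair")
        if self.dilution_range[0] <= 0 or self.dilution_range[0] > self.dilution_range[1]:
            raise ValueError("dilution_range lower bound must be > 0 and <= upper")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_background_taxa < 0 or self.n_background_buckets < 0:
            raise ValueError("background counts must be non-negative")
        if not 0.0 <= self.background_share < 1.0:
            raise ValueError("background_share must lie in [0, 1)")

    @property
    def taxon_ids(self) -> list[str]:
        return [f"taxon_{i + 1:02d}" for i in range(self.n_taxa)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met_{i + 1:02d}" for i in range(self.n_metabolites)]

    @property
    def background_taxon_ids(self) -> list[str]:
        return [f"rare_{i + 1:03d}" for i in range(self.n_background_taxa)]

    @property
    def background_bucket_ids(self) -> list[str]:
        return [f"bgbucket_{i + 1:02d}" for i in range(self.n_background_buckets)]


@dataclass
class PlantedStructure:
    """Ground truth of one generated cohort."""

    block_of_feature: dict[str, int]
    keystone_ids: list[str]
    keystone_blocks: dict[str, tuple[int, int]]
    dilution_factors: dict[str, float]
    he_labels: dict[str, int]
    generating_betas: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedStructure":
        with open(path) as fh:
            d = json.load(fh)
        d["keystone_blocks"] = {k: tuple(v) for k, v in d["keystone_blocks"].items()}
        return cls(**d)


def _latents(spec: SyntheticCohortSpec, rng: np.random.Generator):
    """Latent feature matrix (samples x features) plus the planted map."""
    n = spec.n_cases + spec.n_controls
    feat_ids = spec.taxon_ids + spec.metabolite_ids
    # keystones are metabolite features: linear images of the latents, so the
    # planted bridge correlation survives to the observed scale (taxon counts
    # attenuate correlations through the softmax/multinomial channel, and a
    # taxon can drop out at the mean-abundance filter)
    keystones = (
        spec.metabolite_ids[spec.n_metabolites - spec.n_keystones :]
        if spec.n_keystones
        else []
    )
    regular = [f for f in feat_ids if f not in keystones]

    c = spec.block_factor_corr
    shared = rng.standard_normal((n, 1))
    factors = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.standard_normal(
        (n, spec.n_blocks)
    )
    block_of, ks_blocks = {}, {}
    z = np.empty((n, len(feat_ids)))
    col = {f: i for i, f in enumerate(feat_ids)}
    sq, sq1 = np.sqrt(spec.block_corr), np.sqrt(1 - spec.block_corr)
    for i, f in enumerate(regular):
        b = i % spec.n_blocks
        block_of[f] = b
        z[:, col[f]] = sq * factors[:, b] + sq1 * rng.standard_normal(n)
    for i, f in enumerate(keystones):
        b1, b2 = i % spec.n_blocks, (i + 1) % spec.n_blocks
        block_of[f] = b1
        ks_blocks[f] = (b1, b2)
        bridge = (factors[:, b1] + factors[:, b2]) / np.sqrt(2 * (1 + c))
        z[:, col[f]] = sq * bridge + sq1 * rng.standard_normal(n)
    return z, feat_ids, block_of, keystones, ks_blocks, factors


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[AbundanceTable, NmrBucketMatrix, pd.DataFrame, PlantedStructure]:
    """Draw one cohort: counts table, raw NMR bucket matrix, clinical table.

    Returns the tables together with the :class:`PlantedStructure` ground
    truth. Fully reproducible for a fixed ``spec.seed``.
    """
    spec.validate()
    for f in spec.he_beta:
        if f not in spec.taxon_ids + spec.metabolite_ids:
            raise ValueError(f"he_beta refers to unknown feature {f!r}")

    s_struct, s_counts, s_nmr, s_clin, s_lab = child_seeds(spec.seed, 5)
    n = spec.n_cases + spec.n_controls
    sample_ids = [f"case_{i + 1:02d}" for i in range(spec.n_cases)] + [
        f"ctrl_{i + 1:02d}" for i in range(spec.n_controls)
    ]

    z, feat_ids, block_of, keystones, ks_blocks, factors = _latents(
        spec, np.random.default_rng(s_struct)
    )
    col = {f: i for i, f in enumerate(feat_ids)}

    # --- taxa: structured + background weights -> softmax -> multinomial -----
    # Mean community mass is split between the block-structured taxa
    # (1 - background_share) and the unstructured rare background
    # (background_share); per-sample composition perturbs the structured
    # weights by exp(latent_scale * z).
    rng_c = np.random.default_rng(s_counts)
    w_struct = np.exp(rng_c.normal(0.0, 0.8, size=spec.n_taxa))
    w_struct *= (1.0 - spec.background_share) / w_struct.sum()
    zt = z[:, : spec.n_taxa]
    noise_t = spec.noise_sd * rng_c.standard_normal(zt.shape)
    a_struct = w_struct[None, :] * np.exp(spec.latent_scale * zt + noise_t)
    if spec.n_background_taxa:
        w_bg = np.exp(rng_c.normal(0.0, 0.5, size=spec.n_background_taxa))
        w_bg *= spec.background_share / w_bg.sum()
        # rare taxa fluctuate a lot sample-to-sample (overdispersion), which
        # keeps them from forming a spurious constant-over-total clique
        noise_b = 0.5 * rng_c.standard_normal((n, spec.n_background_taxa))
        a_bg = w_bg[None, :] * np.exp(noise_b)
        abund = np.hstack([a_struct, a_bg])
    else:
        abund = a_struct
    p = abund / abund.sum(axis=1, keepdims=True)
    depths = rng_c.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=n)
    counts = np.vstack([rng_c.multinomial(d, pi) for d, pi in zip(depths, p)])
    taxa = AbundanceTable(
        pd.DataFrame(
            counts,
            index=sample_ids,
            columns=spec.taxon_ids + spec.background_taxon_ids,
        ),
        kind="counts",
    )

    # --- metabolites: linear images of latents + stable background buckets,
    #     everything scaled by the per-sample dilution factor ------------------
    rng_m = np.random.default_rng(s_nmr)
    zm = z[:, spec.n_taxa :]
    levels = 10.0 + zm + spec.noise_sd * rng_m.standard_normal(zm.shape)
    if spec.n_background_buckets:
        bg_base = 20.0 * np.exp(rng_m.normal(0.0, 0.2, size=spec.n_background_buckets))
        # mild multiplicative bucket variation: enough that the background
        # does not form a spurious constant-over-total clique, and tighter
        # than the structured buckets' spread so the PQN median ratio locks
        # onto the background (i.e. onto pure dilution, not block signal)
        bg = bg_base[None, :] * np.exp(
            0.05 * rng_m.standard_normal((n, spec.n_background_buckets))
        )
        levels = np.hstack([levels, bg])
    dil = rng_m.uniform(*spec.dilution_range, size=n)
    nmr_vals = np.clip(levels, 0.0, None) * dil[:, None]
    n_buckets = spec.n_metabolites + spec.n_background_buckets
    centers = 1.00 + 0.25 * np.arange(n_buckets)
    edges = [(c - 0.01, c + 0.01) for c in centers]
    nmr = NmrBucketMatrix(
        pd.DataFrame(
            nmr_vals,
            index=sample_ids,
            columns=spec.metabolite_ids + spec.background_bucket_ids,
        ),
        edges,
        "raw",
        provenance=["synthetic"],
    )

    # --- clinical table ------------------------------------------------------
    rng_cl = np.random.default_rng(s_clin)
    group = ["cirrhotic"] * spec.n_cases + ["control"] * spec.n_controls
    clinical = pd.DataFrame(index=sample_ids)
    clinical["group"] = group
    # MELD tracks the first block factor (r = 0.8 on the latent scale);
    # remaining parameters are independent noise on realistic scales.
    clinical["MELD"] = 15 + 5 * (0.8 * factors[:, 0] + 0.6 * rng_cl.standard_normal(n))
    clinical["CRP"] = np.exp(rng_cl.normal(1.0, 0.6, size=n))
    clinical["IL6"] = np.exp(rng_cl.normal(1.5, 0.7, size=n))
    clinical["WBC"] = rng_cl.normal(6.0, 1.5, size=n)
    clinical["cardiac_frequency"] = rng_cl.normal(75, 10, size=n)

    # --- HE labels from the logistic model on feature latents ----------------
    rng_l = np.random.default_rng(s_lab)
    eta = np.full(n, spec.he_intercept)
    for f, beta in spec.he_beta.items():
        eta += beta * z[:, col[f]]
    p_he = 1.0 / (1.0 + np.exp(-eta))
    he = (rng_l.random(n) < p_he).astype(int)
    clinical["HE"] = he

    planted = PlantedStructure(
        block_of_feature=dict(block_of),
        keystone_ids=list(keystones),
        keystone_blocks=dict(ks_blocks),
        dilution_factors=dict(zip(sample_ids, dil.tolist())),
        he_labels=dict(zip(sample_ids, he.tolist())),
        generating_betas=dict(spec.he_beta),
    )
    return taxa, nmr, clinical, planted


def generate_raw_spectrum(
    peaks: list[tuple[float, float, float]],
    ppm_grid: np.ndarray,
    baseline_amplitude: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    sample_id: str = "synthetic",
) -> Spectrum:
    """Sum of Gaussian peaks + smooth low-frequency baseline + white noise.

    ``peaks`` are (ppm_center, width_sigma, area) triples; peak areas are
    recoverable by numerical integration. A fixture generator for the NMR
    preprocessing stages.
    """
    grid = np.asarray(ppm_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or not ((np.diff(grid) > 0).all() or (np.diff(grid) < 0).all()):
        raise ValueError("ppm_grid must be a strictly monotone vector")
    lo, hi = min(grid[0], grid[-1]), max(grid[0], grid[-1])
    y = np.zeros_like(grid)
    for center, width, area in peaks:
        if width <= 0:
            raise ValueError("peak widths must be positive")
        if not lo <= center <= hi:
            raise ValueError(f"peak at {center} ppm lies outside the grid")
        y += area / (width * np.sqrt(2 * np.pi)) * np.exp(-((grid - center) ** 2) / (2 * width**2))
    rng = np.random.default_rng(seed)
    if baseline_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        x = (grid - lo) / (hi - lo)
        y += baseline_amplitude * 0.5 * (1 + np.sin(2 * np.pi * 1.5 * x + phase))
    if noise_sd:
        y += rng.normal(0.0, noise_sd, size=len(grid))
    return Spectrum(grid, y, sample_id)


def write_cohort(
    out_dir,
    taxa: AbundanceTable,
    nmr: NmrBucketMatrix,
    clinical: pd.DataFrame,
    planted: PlantedStructure,
    spec: SyntheticCohortSpec,
) -> dict[str, Path]:
    """Write the three tables as TSV (with a ``#seed=`` header) + planted JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    head = [f"seed={spec.seed}"]
    paths = {
        "taxa": out / "taxa_counts.tsv",
        "nmr": out / "nmr_buckets.tsv",
        "clinical": out / "clinical.tsv",
        "planted": out / "planted.json",
    }
    taxa.write(paths["taxa"], head)
    nmr.write(paths["nmr"], head)
    write_table(clinical, paths["clinical"], head)
    planted.to_json(paths["planted"])
    return paths
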