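"""Synthetic paired GWAS summary statistics with known causal structure.

The generator emulates a two-sample MR design: an exposure GWAS and an
outcome GWAS measured in non-overlapping samples, linked per variant j by

    alpha_j = true_beta * gamma_j + delta_j

where gamma_j ~ Normal(0, gamma_sd^2) is the true exposure effect and
delta_j is a direct (horizontally pleiotropic) effect on the outcome, drawn
Normal(pleiotropy_mean, pleiotropy_sd^2) with probability
``pleiotropy_fraction`` and zero otherwise. Standard errors follow the
standard summary-statistic approximation se = 1/sqrt(2 N maf (1-maf)), and
observed effects add independent noise on each side (no sample overlap).

On top of the clean pair the outcome file is corrupted the way real
consortium files disagree: random allele swaps (sign flips), random strand
flips (reverse-complemented alleles), and a configurable fraction of
palindromic A/T / C/G variants. Every corruption is logged in a truth
manifest so harmonization can be checked exactly. Variants are laid out in
LD blocks on one synthetic chromosome: block-mates sit within the clumping
window and share r^2 = ``ld_r2``; blocks are separated by more than the
window and are uncorrelated.

Defaults encode the study conditions this package is exercised under: 50
variants, causal effect 0.2 on the log-odds scale, exposure GWAS of 186,689
(a large PTSD symptom-severity GWAS) and outcome GWAS of 440,328 (a large
ischemic-stroke case-control meta-analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .instruments import LDMatrix
from .summary_io import ColumnMap, SummaryStats, VariantAssociation, write_summary_stats

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_CHOICES = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_BLOCK_SPACING_BP = 10_000_000  # between block starts; > any sane clump window
_WITHIN_BLOCK_BP = 10_000

_MIN_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class CorruptionConfig:
    """Probabilities of allele-coding damage injected into the outcome file."""

    sign_flip_prob: float = 0.25
    strand_flip_prob: float = 0.10
    palindromic_fraction: float = 0.20


@dataclass(frozen=True)
class SimulationConfig:
    n_snp: int = 50
    true_beta: float = 0.2
    n_exposure: int = 186_689
    n_outcome: int = 440_328
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05
    pleiotropy_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_snp < 1:
            bad.append("n_snp must be >= 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            bad.append("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            bad.append("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.gamma_sd <= 0:
            bad.append("gamma_sd must be positive")
        for name in ("pleiotropy_fraction",):
            if not (0.0 <= getattr(self, name) <= 1.0):
                bad.append(f"{name} must be in [0,1]")
        if self.pleiotropy_sd < 0:
            bad.append("pleiotropy_sd must be >= 0")
        if self.ld_block_size < 1:
            bad.append("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_r2 <= 1.0):
            bad.append("ld_r2 must be in [0,1]")
        c = self.corruption
        for name in ("sign_flip_prob", "strand_flip_prob", "palindromic_fraction"):
            if not (0.0 <= getattr(c, name) <= 1.0):
                bad.append(f"corruption.{name} must be in [0,1]")
        if bad:
            raise ValueError("invalid SimulationConfig: " + "; ".join(bad))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated pair, including the corruption manifest."""

    config: SimulationConfig
    table: pd.DataFrame
    # columns: variant_id, block, maf, gamma_true, delta, pleiotropic,
    #          palindromic, sign_flipped, strand_flipped, alpha_hat_clean

    @property
    def true_beta(self) -> float:
        return self.config.true_beta

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.15g")


def _variant_ids(n_snp: int) -> list[str]:
    return [f"rs{1000 + j}" for j in range(n_snp)]


def _positions(n_snp: int, block_size: int) -> tuple[np.ndarray, np.ndarray]:
    j = np.arange(n_snp)
    block = j // block_size
    pos = 1 + block * _BLOCK_SPACING_BP + (j % block_size) * _WITHIN_BLOCK_BP
    return block, pos


def simulate_pair(
    config: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SimulationTruth]:
    """Generate one exposure/outcome summary-statistics pair plus its truth.

    Fully reproducible: the same config (including seed) yields byte-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_snp
    ids = _variant_ids(k)
    block, pos = _positions(k, config.ld_block_size)

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=k)
    gamma_true = rng.normal(0.0, config.gamma_sd, size=k)
    # exact-count design: round(fraction * k) variants are pleiotropic, so a
    # "30% invalid" or "one planted outlier" scenario holds by construction
    n_pleio = int(round(config.pleiotropy_fraction * k))
    pleiotropic = np.zeros(k, dtype=bool)
    pleiotropic[rng.permutation(k)[:n_pleio]] = True
    delta = np.where(
        pleiotropic, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k), 0.0
    )
    se_g = 1.0 / np.sqrt(2.0 * config.n_exposure * maf * (1.0 - maf))
    se_a = 1.0 / np.sqrt(2.0 * config.n_outcome * maf * (1.0 - maf))
    gamma_hat = gamma_true + rng.normal(0.0, se_g)
    alpha_true = config.true_beta * gamma_true + delta
    alpha_hat = alpha_true + rng.normal(0.0, se_a)

    palindromic = rng.random(k) < config.corruption.palindromic_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_CHOICES), size=k)
    nonpal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=k)
    alleles = [
        _PALINDROMIC_CHOICES[pal_choice[j]] if palindromic[j] else _NONPALINDROMIC_PAIRS[nonpal_choice[j]]
        for j in range(k)
    ]

    # outcome-side allele frequency carries a small estimation wobble, enough
    # to be realistic but not to flip the minor-allele side outside the
    # palindromic ambiguity band
    eaf_out = np.clip(maf + rng.normal(0.0, 0.005, size=k), 1e-3, 1 - 1e-3)

    sign_flip = rng.random(k) < config.corruption.sign_flip_prob
    strand_flip = rng.random(k) < config.corruption.strand_flip_prob

    exp_records = []
    out_records = []
    for j in range(k):
        ea, oa = alleles[j]
        p_exp = max(2.0 * sps.norm.sf(abs(gamma_hat[j]) / se_g[j]), _MIN_P)
        p_out = max(2.0 * sps.norm.sf(abs(alpha_hat[j]) / se_a[j]), _MIN_P)
        exp_records.append(
            VariantAssociation(
                variant_id=ids[j], chrom="1", pos=int(pos[j]),
                effect_allele=ea, other_allele=oa, eaf=float(maf[j]),
                beta=float(gamma_hat[j]), se=float(se_g[j]), pvalue=float(p_exp),
                n=float(config.n_exposure),
            )
        )
        o_ea, o_oa = ea, oa
        o_beta, o_eaf = float(alpha_hat[j]), float(eaf_out[j])
        if sign_flip[j]:
            o_ea, o_oa = o_oa, o_ea
            o_beta = -o_beta
            o_eaf = 1.0 - o_eaf
        if strand_flip[j]:
            o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
        out_records.append(
            VariantAssociation(
                variant_id=ids[j], chrom="1", pos=int(pos[j]),
                effect_allele=o_ea, other_allele=o_oa, eaf=o_eaf,
                beta=o_beta, se=float(se_a[j]), pvalue=float(p_out),
                n=float(config.n_outcome),
            )
        )

    exposure = SummaryStats(
        trait_name="synthetic_exposure", records=exp_records,
        trait_type="quantitative", ancestry="synthetic",
    )
    outcome = SummaryStats(
        trait_name="synthetic_outcome", records=out_records,
        trait_type="binary", ancestry="synthetic",
    )
    truth_table = pd.DataFrame(
        {
            "variant_id": ids,
            "block": block,
            "maf": maf,
            "gamma_true": gamma_true,
            "delta": delta,
            "pleiotropic": pleiotropic,
            "palindromic": palindromic,
            "sign_flipped": sign_flip,
            "strand_flipped": strand_flip,
            "alpha_hat_clean": alpha_hat,
        }
    )
    return exposure, outcome, SimulationTruth(config=config, table=truth_table)


def simulate_ld_blocks(config: SimulationConfig) -> LDMatrix:
    """Block-diagonal LD consistent with :func:`simulate_pair`'s layout.

    Within-block r^2 is ``ld_r2``, off-block 0, diagonal 1; positions are
    assigned so that block-mates fall inside a 1000 kb clumping window.
    """
    config.validate()
    k = config.n_snp
    block, _ = _positions(k, config.ld_block_size)
    r2 = np.where(block[:, None] == block[None, :], config.ld_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(_variant_ids(k), r2)


_FIXTURE_SCENARIOS: dict[str, SimulationConfig] = {
    "valid_instruments": SimulationConfig(seed=101),
    "directional_pleiotropy": SimulationConfig(
        pleiotropy_fraction=1.0, pleiotropy_mean=0.05, pleiotropy_sd=0.02, seed=102
    ),
    "planted_outlier": SimulationConfig(
        n_snp=10, pleiotropy_fraction=0.1, pleiotropy_mean=0.5, pleiotropy_sd=1e-3,
        # no palindromes here so the planted SNP can never be frequency-dropped
        corruption=CorruptionConfig(palindromic_fraction=0.0),
        seed=103,
    ),
    "corruption_heavy": SimulationConfig(
        corruption=CorruptionConfig(
            sign_flip_prob=0.5, strand_flip_prob=0.5, palindromic_fraction=0.3
        ),
        seed=104,
    ),
}


def make_fixture_suite(out_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Write a small deterministic fixture set for tests and documentation.

    For each scenario writes ``<name>.exposure.tsv``, ``<name>.outcome.tsv``,
    ``<name>.truth.tsv`` and ``<name>.config.yaml``. Regeneration is
    byte-identical (pinned per-scenario seeds).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = ColumnMap()
    written: dict[str, dict[str, Path]] = {}
    for name, cfg in _FIXTURE_SCENARIOS.items():
        exposure, outcome, truth = simulate_pair(cfg)
        paths = {
            "exposure": out_dir / f"{name}.exposure.tsv",
            "outcome": out_dir / f"{name}.outcome.tsv",
            "truth": out_dir / f"{name}.truth.tsv",
            "config": out_dir / f"{name}.config.yaml",
        }
        write_summary_stats(exposure, paths["exposure"], cmap)
        write_summary_stats(outcome, paths["outcome"], cmap)
        truth.write(paths["truth"])
        doc = asdict(cfg)
        doc["maf_range"] = list(doc["maf_range"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(doc, fh)
        written[name] = paths
    return written


__all__ = [
    "CorruptionConfig",
    "SimulationConfig",
    "SimulationTruth",
    "make_fixture_suite",
    "simulate_ld_blocks",
    "simulate_pair",
]
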