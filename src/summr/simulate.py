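"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the summary-data structure two-sample MR consumes:
for each instrument j an allele frequency p_j, a true per-allele exposure
effect gamma_j (standardized scale), an optional direct (pleiotropic)
effect alpha_j on the outcome, and the induced outcome effect
Gamma_j = theta * gamma_j + alpha_j.  Observed effects add sampling noise
with the analytic standardized-trait SE, sigma = 1/sqrt(2 p (1-p) n), so
instrument strength scales as sqrt(n).

Directional pleiotropy is planted *relative to the observed
exposure-increasing allele* (alpha_j enters as
sign(gamma_hat_j) * N(mu_alpha, sd_alpha^2)), the orientation in which
published instrument sets are reported; with symmetric gamma this is the
convention under which directional pleiotropy actually biases IVW upward
while the MR-Egger intercept estimates the average direct effect.

Allele-encoding corruptions reproduce real data-source quirks on the
outcome table: effect/other allele swaps, strand flips, and palindromic
(A/T, G/C) variants planted with intermediate allele frequencies that
harmonization must remove.

Reproducibility: every SNP draws from its own `numpy` PCG64 stream seeded
as (root seed, SNP index), so regenerating with the same config is exact
and adding SNPs never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .gwas_io import GWASTable
from .harmonize import COMPLEMENT

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

#: minimum representable two-sided p (avoids exact zeros for huge z-scores)
_P_FLOOR = 1e-300

ENCODING_NONE = "none"
ENCODING_SWAP = "swap"
ENCODING_FLIP = "strand_flip"
ENCODING_PALINDROME = "palindrome_intermediate"


@dataclass
class SimulationConfig:
    """Generative parameters for one paired exposure/outcome study."""

    J: int = 50
    theta: float = 0.2
    gamma_sd: float = 0.2
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: int = 100_000
    n_out: int = 100_000
    eaf_range: tuple[float, float] = (0.1, 0.9)
    encode_swaps: float = 0.0
    encode_strand_flips: float = 0.0
    encode_palindromes: float = 0.0
    binary_outcome: bool = False
    n_outliers: int = 0
    outlier_scale: float = 10.0
    reverse_roles: bool = False
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.J < 1:
            raise InputError("J must be >= 1")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise InputError("sample sizes must be positive")
        for name in ("pleiotropy_frac", "encode_swaps", "encode_strand_flips", "encode_palindromes"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if (self.encode_swaps + self.encode_strand_flips + self.encode_palindromes) > 1:
            raise InputError("encoding fractions must sum to at most 1")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise InputError("eaf_range must satisfy 0 < low < high < 1")
        return self


@dataclass
class SimulatedStudy:
    """A paired exposure/outcome study plus the generating truth."""

    exposure: GWASTable
    outcome: GWASTable
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)


def _two_sided_p(beta: float, se: float) -> float:
    return max(float(2 * stats.norm.sf(abs(beta) / se)), _P_FLOOR)


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study according to ``config``.

    ``truth`` records, per SNP: the true gamma and alpha (on the stored
    orientation), the planted encoding, and the clean harmonized pair
    values an exact harmonization must recover; plus the set of invalid
    (pleiotropic) SNP ids and the true causal direction
    (``A_to_B``/``B_to_A`` in the argument order of a bidirectional run).
    """
    config.validate()
    lo, hi = config.eaf_range

    exp_rows, out_rows, clean_rows = [], [], []
    gammas = np.empty(config.J)
    alphas = np.empty(config.J)
    encodings: dict[str, str] = {}
    invalid: list[str] = []

    for j in range(config.J):
        rng = np.random.default_rng([config.seed, j])
        snp = f"snp{j:05d}"
        eaf = rng.uniform(lo, hi)
        gamma = rng.normal(0.0, config.gamma_sd) if config.gamma_sd > 0 else 0.0
        is_pleio = rng.uniform() < config.pleiotropy_frac
        alpha_oriented = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd) \
            if config.pleiotropy_sd > 0 else config.pleiotropy_mean
        noise_x = rng.normal()
        noise_y = rng.normal()
        allele_pick = rng.integers(len(_NONPALINDROMIC_PAIRS))
        u_encode = rng.uniform()
        pal_pick = rng.integers(2)
        pal_eaf = rng.uniform(0.44, 0.56)

        encoding = ENCODING_NONE
        if u_encode < config.encode_swaps:
            encoding = ENCODING_SWAP
        elif u_encode < config.encode_swaps + config.encode_strand_flips:
            encoding = ENCODING_FLIP
        elif u_encode < config.encode_swaps + config.encode_strand_flips + config.encode_palindromes:
            encoding = ENCODING_PALINDROME
            eaf = pal_eaf

        sigma_x = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_exp)
        sigma_y = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * config.n_out)
        gamma_hat = gamma + sigma_x * noise_x

        # direct effects are planted relative to the *observed*
        # exposure-increasing allele — the orientation in which published
        # instrument sets report directional pleiotropy
        sign = 1.0 if gamma_hat >= 0 else -1.0
        alpha = sign * alpha_oriented if is_pleio else 0.0
        if j < config.n_outliers:  # deterministic planted gross outliers
            alpha = sign * config.outlier_scale * sigma_y
        if alpha != 0.0:
            invalid.append(snp)

        big_gamma = config.theta * gamma + alpha
        big_gamma_hat = big_gamma + sigma_y * noise_y

        if encoding == ENCODING_PALINDROME:
            ea, oa = ("A", "T") if pal_pick == 0 else ("G", "C")
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[allele_pick]

        gammas[j], alphas[j] = gamma, alpha
        encodings[snp] = encoding
        exp_rows.append({
            "snp_id": snp, "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": gamma_hat, "se": sigma_x, "pval": _two_sided_p(gamma_hat, sigma_x),
            "n": config.n_exp,
        })
        clean_rows.append({
            "snp_id": snp, "beta_exp": gamma_hat, "se_exp": sigma_x,
            "beta_out": big_gamma_hat, "se_out": sigma_y, "eaf": eaf,
            "encoding": encoding,
        })
        # apply the planted encoding quirk to the outcome record
        ea_o, oa_o, b_o, f_o = ea, oa, big_gamma_hat, eaf
        if encoding == ENCODING_SWAP:
            ea_o, oa_o, b_o, f_o = oa, ea, -big_gamma_hat, 1 - eaf
        elif encoding == ENCODING_FLIP:
            ea_o, oa_o = COMPLEMENT[ea], COMPLEMENT[oa]
        out_rows.append({
            "snp_id": snp, "effect_allele": ea_o, "other_allele": oa_o, "eaf": f_o,
            "beta": b_o, "se": sigma_y, "pval": _two_sided_p(b_o, sigma_y),
            "n": config.n_out,
        })

    causal = GWASTable(
        trait_name="trait_A", data=pd.DataFrame(exp_rows),
        n_total=config.n_exp, trait_unit="SD",
    )
    downstream = GWASTable(
        trait_name="trait_B", data=pd.DataFrame(out_rows),
        n_total=config.n_out, is_binary=config.binary_outcome,
        trait_unit="log-odds" if config.binary_outcome else "SD",
    )
    truth = {
        "theta": config.theta,
        "gamma": gammas,
        "alpha": alphas,
        "invalid_ids": invalid,
        "encodings": encodings,
        "clean_pairs": pd.DataFrame(clean_rows),
        "true_direction": "A_to_B",
    }
    if config.reverse_roles:
        causal, downstream = downstream, causal
        causal.trait_name, downstream.trait_name = "trait_A", "trait_B"
        truth["true_direction"] = "B_to_A"
    return SimulatedStudy(exposure=causal, outcome=downstream, truth=truth, config=config)


SCENARIOS = (
    "null", "causal", "balanced_pleiotropy", "directional_pleiotropy",
    "single_outlier", "reverse_causal",
)


def scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Frozen study conditions for the validation scenarios.

    All use J = 50 instruments with gamma_sd = 0.2 and n = 100,000 per side
    (a strong-instrument regime; see the methods note), differing only in
    the causal effect and pleiotropy structure:

    * ``null`` — theta = 0, no pleiotropy.
    * ``causal`` — theta = 0.2, no pleiotropy.
    * ``balanced_pleiotropy`` — theta = 0.2; 30% of SNPs carry mean-zero
      direct effects (sd 0.01).
    * ``directional_pleiotropy`` — theta = 0.2; 30% of SNPs carry direct
      effects ~ N(0.02, 0.01^2) on the exposure-increasing allele.
    * ``single_outlier`` — theta = 0.2; exactly one SNP with a direct
      effect of 10 outcome-SEs.
    * ``reverse_causal`` — theta = 0.2 generated from trait B to trait A
      (roles swapped), for bidirectional testing.
    """
    base = dict(J=50, theta=0.2, gamma_sd=0.2, n_exp=100_000, n_out=100_000, seed=seed)
    table = {
        "null": dict(base, theta=0.0),
        "causal": base,
        "balanced_pleiotropy": dict(base, pleiotropy_frac=0.3, pleiotropy_mean=0.0,
                                    pleiotropy_sd=0.01),
        "directional_pleiotropy": dict(base, pleiotropy_frac=0.3, pleiotropy_mean=0.02,
                                       pleiotropy_sd=0.01),
        "single_outlier": dict(base, n_outliers=1, outlier_scale=10.0),
        "reverse_causal": dict(base, reverse_roles=True),
    }
    if name not in table:
        raise InputError(f"unknown scenario '{name}'; valid names: {', '.join(SCENARIOS)}")
    return SimulationConfig(**table[name])
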