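"""Synthetic multi-platform callset generator.

Emulates the statistical structure of a pharmacogene validation study:
diploid genotypes at biallelic pharmacogene-like sites drawn under
Hardy-Weinberg equilibrium, an exome-style test callset with overdispersed
read depths, a binomial read-level error model with Phred-scaled genotype
qualities, per-site VQSR tranche labels with tranche-dependent genotype
corruption, an amplicon-style truth callset with a missing/under-depth
fraction, and a genotyping-panel callset with per-call call-rate noise.

Every injected genotype corruption is recorded in a ledger, so pipeline
recovery (the measured discordance per tranche vs the injected rate) is
directly testable.

Determinism: one global seed governs all draws.  Each generation stage
derives an independent child generator from ``(seed, stage_id)`` with a
frozen stage order (sites, true genotypes, truth observation, test
observation, panel observation, targets), so identical seed + config give
byte-identical outputs, and regenerating one stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .callset_model import (
    Allele,
    Callset,
    GenotypeCall,
    HET,
    HOM_ALT,
    HOM_REF,
    NO_CALL_ALLELES,
    Platform,
    Tranche,
    VariantSite,
)
from .errors import ConfigError
from .io_formats import TargetIntervals

# frozen stage order (D22): child seeds are (seed, stage_id)
_STAGE_SITES = 0
_STAGE_GENOTYPES = 1
_STAGE_TRUTH_OBS = 2
_STAGE_TEST_OBS = 3
_STAGE_PANEL_OBS = 4
_STAGE_TARGETS = 5

_GENOTYPE_ALLELES = {0: HOM_REF, 1: HET, 2: HOM_ALT}
_TRANCHES = (Tranche.PASS_99, Tranche.TRANCHE_99_999, Tranche.ABOVE_999)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cross-platform experiment.

    Defaults mirror a 36-sample, 43-site pharmacogene validation: roughly
    63% of sites pass-filter and 37% in the 99-99.9% tranche, a per-call
    genotype-corruption probability of 0.4% for pass-filter calls versus
    26% inside the tranche (the observed strict-vs-relaxed discordance
    contrast), ~1% panel corruption, and a few percent of truth calls
    absent or under-depth.
    """

    n_samples: int = 36
    n_sites: int = 43
    #: per-site alt-allele frequency: scalar, per-site list, or a sampler
    #: spec ("uniform", lo, hi) / ("beta", a, b)
    allele_freqs: float | Sequence[float] | tuple = ("uniform", 0.05, 0.5)
    mean_depth: float = 50.0
    depth_dispersion: float = 5.0       # NB shape; larger = less overdispersed
    min_depth: int = 0                  # floor applied after the NB draw
    base_error: float = 0.01            # per-read miscall probability
    tranche_fractions: tuple[float, float, float] = (27 / 43, 16 / 43, 0.0)
    error_rate_pass: float = 0.004
    error_rate_tranche: float = 0.26
    missing_truth_rate: float = 0.04
    truth_mean_depth: float = 250.0
    panel_call_rate_params: tuple[float, float] = (38.0, 2.0)  # Beta(a, b) x 100
    panel_error_rate: float = 0.011
    panel_absent_fraction: float = 0.0  # sites dropped from the panel roster
    n_panel_only_sites: int = 0         # extra panel sites absent from the exome
    indel_fraction: float = 0.1
    on_target_fraction: float = 0.8
    contig: str = "chr22"
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_samples < 1:
            bad.append("n_samples")
        if self.n_sites < 1:
            bad.append("n_sites")
        for name in ("base_error", "error_rate_pass", "error_rate_tranche",
                     "missing_truth_rate", "panel_error_rate",
                     "panel_absent_fraction", "indel_fraction", "on_target_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        if not math.isclose(sum(self.tranche_fractions), 1.0, abs_tol=1e-9) or any(
            f < 0 for f in self.tranche_fractions
        ):
            bad.append("tranche_fractions")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0 or self.truth_mean_depth <= 0:
            bad.append("mean_depth/depth_dispersion/truth_mean_depth")
        if min(self.panel_call_rate_params) <= 0:
            bad.append("panel_call_rate_params")
        if isinstance(self.allele_freqs, (int, float)):
            if not 0.0 <= float(self.allele_freqs) <= 1.0:
                bad.append("allele_freqs")
        elif not (isinstance(self.allele_freqs, tuple)
                  and self.allele_freqs and isinstance(self.allele_freqs[0], str)):
            if len(self.allele_freqs) != self.n_sites or any(
                not 0.0 <= q <= 1.0 for q in self.allele_freqs
            ):
                bad.append("allele_freqs")
        if bad:
            raise ConfigError(f"invalid simulation config fields: {', '.join(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("allele_freqs", "tranche_fractions", "panel_call_rate_params"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


@dataclass(frozen=True)
class GenotypeLikelihoodModel:
    """Flat-prior diploid binomial genotype likelihood.

    Each read carries the alternate allele with probability epsilon,
    one-half or 1 - epsilon under the hom-ref, het and hom-alt genotypes
    respectively; the per-read emission probabilities for each genotype
    class therefore sum to one.
    """

    base_error: float = 0.01

    def alt_read_probs(self) -> np.ndarray:
        e = self.base_error
        return np.array([e, 0.5, 1.0 - e])


def genotype_quality(
    ref_reads: int,
    alt_reads: int,
    model: GenotypeLikelihoodModel,
) -> tuple[tuple[Allele, Allele], Optional[int]]:
    """Call a genotype and its Phred-scaled quality from read counts.

    The call is the maximum-likelihood genotype class under a flat prior;
    GQ is the Phred-scaled posterior probability that the call is wrong,
    capped at 99.  Likelihood ties break toward the lower-dosage class.
    Zero total reads give a no-call with GQ absent.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be >= 0")
    depth = ref_reads + alt_reads
    if depth == 0:
        return NO_CALL_ALLELES, None
    with np.errstate(divide="ignore"):
        loglik = binom.logpmf(alt_reads, depth, model.alt_read_probs())
    best = int(np.argmax(loglik))
    log_post = loglik - logsumexp(loglik)
    post_error = -np.expm1(log_post[best])   # 1 - posterior, stable near 1
    if post_error <= 0:
        gq = 99
    else:
        gq = min(99, int(round(-10.0 * math.log10(post_error))))
    return _GENOTYPE_ALLELES[best], gq


# ---------------------------------------------------------------------------
# site and genotype generation

_BASES = "ACGT"


def generate_sites(config: SimulationConfig) -> tuple[list[VariantSite], np.ndarray]:
    """Deterministically generate the site roster and per-site alt frequencies."""
    config.validate()
    rng = _stage_rng(config, _STAGE_SITES)
    sites: list[VariantSite] = []
    pos = 42_000_000
    for i in range(config.n_sites):
        pos += int(rng.integers(200, 2000))
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        ref, alt = _BASES[ref_i], _BASES[alt_i]
        if rng.random() < config.indel_fraction:
            if rng.random() < 0.5:
                ref, alt = ref + alt, ref        # deletion, anchored
            else:
                ref, alt = ref, ref + alt        # insertion
        sites.append(VariantSite(
            contig=config.contig, position=pos, ref=ref, alt=alt,
            rsid=f"rs{9_000_000 + i}",
            gene="CYP2D6" if i % 2 == 0 else "CYP2C19",
        ))
    freqs = _draw_freqs(config, rng)
    return sites, freqs


def _draw_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.allele_freqs
    if isinstance(spec, (int, float)):
        return np.full(config.n_sites, float(spec))
    if isinstance(spec, tuple) and spec and isinstance(spec[0], str):
        kind = spec[0]
        if kind == "uniform":
            return rng.uniform(spec[1], spec[2], size=config.n_sites)
        if kind == "beta":
            return rng.beta(spec[1], spec[2], size=config.n_sites)
        raise ConfigError(f"unknown allele_freqs sampler {kind!r}")
    return np.asarray(spec, dtype=float)


def _true_genotypes(config: SimulationConfig, freqs: np.ndarray) -> np.ndarray:
    """(n_sites, n_samples) alt-allele dosages under Hardy-Weinberg."""
    rng = _stage_rng(config, _STAGE_GENOTYPES)
    # two independent allele draws per individual == HWE by construction
    return rng.binomial(2, freqs[:, None], size=(config.n_sites, config.n_samples))


def _sample_names(config: SimulationConfig) -> list[str]:
    return [f"S{i:03d}" for i in range(1, config.n_samples + 1)]


def generate_truth(config: SimulationConfig) -> Callset:
    """Amplicon-style truth callset with deep depths and a missing fraction.

    Truth depths are Poisson around ``truth_mean_depth`` (well above the
    10-fold confidence floor); a ``missing_truth_rate`` fraction of calls
    is either absent from the callset or assigned an under-threshold depth
    (half/half), exercising the missing-truth routing downstream.
    """
    sites, freqs = generate_sites(config)
    dosages = _true_genotypes(config, freqs)
    rng = _stage_rng(config, _STAGE_TRUTH_OBS)
    samples = _sample_names(config)
    callset = Callset(platform=Platform.TRUTH_AMPLICON)
    callset.samples.extend(samples)
    for i, site in enumerate(sites):
        callset.add_site(site)
        for j, sample in enumerate(samples):
            dp = max(10, int(rng.poisson(config.truth_mean_depth)))
            missing = rng.random() < config.missing_truth_rate
            if missing:
                if rng.random() < 0.5:
                    continue                      # truth record absent
                dp = int(rng.integers(0, 10))     # under-depth
            callset.add(GenotypeCall(
                sample=sample, site=site, alleles=_GENOTYPE_ALLELES[int(dosages[i, j])],
                platform=Platform.TRUTH_AMPLICON, dp=dp,
            ))
    return callset


@dataclass(frozen=True)
class InjectedError:
    """Ledger entry for one deliberate genotype corruption."""

    sample: str
    site: VariantSite
    tranche: Tranche
    alleles_before: tuple[Allele, Allele]
    alleles_after: tuple[Allele, Allele]


@dataclass
class TestSimulation:
    """An exome-style callset plus the hidden ledger of injected errors."""

    callset: Callset
    injected_errors: list[InjectedError] = field(default_factory=list)
    site_tranches: dict[tuple, Tranche] = field(default_factory=dict)


def simulate_test_callset(truth: Callset, config: SimulationConfig) -> TestSimulation:
    """Simulate the exome platform against the truth genotypes.

    Per call: depth is negative-binomial around ``mean_depth`` (floored at
    ``min_depth``), alternate reads are binomial given the true dosage and
    ``base_error``, the genotype and GQ come from the likelihood model, and
    with the per-tranche corruption probability the emitted genotype is
    replaced by a uniformly chosen different class and logged in the
    ledger.  Each site draws one VQSR tranche from ``tranche_fractions``.
    """
    config.validate()
    sites, freqs = generate_sites(config)
    dosages = _true_genotypes(config, freqs)
    rng = _stage_rng(config, _STAGE_TEST_OBS)
    model = GenotypeLikelihoodModel(base_error=config.base_error)
    error_rates = {
        Tranche.PASS_99: config.error_rate_pass,
        Tranche.TRANCHE_99_999: config.error_rate_tranche,
        Tranche.ABOVE_999: config.error_rate_tranche,
    }
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.mean_depth)
    samples = _sample_names(config)
    alt_probs = model.alt_read_probs()

    sim = TestSimulation(callset=Callset(platform=Platform.TEST_WES))
    sim.callset.samples.extend(samples)
    for i, site in enumerate(sites):
        tranche = _TRANCHES[int(rng.choice(3, p=config.tranche_fractions))]
        sim.site_tranches[site.key] = tranche
        sim.callset.add_site(site)
        for j, sample in enumerate(samples):
            depth = max(config.min_depth, int(rng.negative_binomial(nb_n, nb_p)))
            dosage = int(dosages[i, j])
            alt_reads = int(rng.binomial(depth, alt_probs[dosage])) if depth else 0
            ref_reads = depth - alt_reads
            alleles, gq = genotype_quality(ref_reads, alt_reads, model)
            if alleles != NO_CALL_ALLELES and rng.random() < error_rates[tranche]:
                called = [g for g, a in _GENOTYPE_ALLELES.items() if a == alleles][0]
                wrong = [g for g in (0, 1, 2) if g != called]
                corrupted = _GENOTYPE_ALLELES[int(rng.choice(wrong))]
                sim.injected_errors.append(InjectedError(
                    sample=sample, site=site, tranche=tranche,
                    alleles_before=alleles, alleles_after=corrupted,
                ))
                alleles = corrupted
            sim.callset.add(GenotypeCall(
                sample=sample, site=site, alleles=alleles, platform=Platform.TEST_WES,
                ref_reads=ref_reads, alt_reads=alt_reads, gq=gq, tranche=tranche,
            ))
    return sim


def simulate_panel_callset(truth: Callset, config: SimulationConfig) -> Callset:
    """Simulate the genotyping panel from the same true genotypes.

    Genotypes are copied from the truth dosages and corrupted at
    ``panel_error_rate``; call rates are Beta draws scaled to percent.  A
    ``panel_absent_fraction`` of sites is dropped from the panel roster and
    ``n_panel_only_sites`` extra sites (absent from the exome) appended, so
    site matching is exercised in both directions.
    """
    config.validate()
    sites, freqs = generate_sites(config)
    dosages = _true_genotypes(config, freqs)
    rng = _stage_rng(config, _STAGE_PANEL_OBS)
    a, b = config.panel_call_rate_params
    samples = _sample_names(config)
    callset = Callset(platform=Platform.PANEL)
    callset.samples.extend(samples)
    for i, site in enumerate(sites):
        if rng.random() < config.panel_absent_fraction:
            continue
        callset.add_site(site)
        for j, sample in enumerate(samples):
            dosage = int(dosages[i, j])
            if rng.random() < config.panel_error_rate:
                dosage = int(rng.choice([g for g in (0, 1, 2) if g != dosage]))
            callset.add(GenotypeCall(
                sample=sample, site=site, alleles=_GENOTYPE_ALLELES[dosage],
                platform=Platform.PANEL,
                call_rate=round(float(100.0 * rng.beta(a, b)), 1),
            ))
    pos = 50_000_000
    for k in range(config.n_panel_only_sites):
        pos += int(rng.integers(500, 5000))
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        site = VariantSite(contig=config.contig, position=pos,
                           ref=_BASES[ref_i], alt=_BASES[alt_i],
                           rsid=f"rs{8_000_000 + k}", gene="ADME_PANEL")
        callset.add_site(site)
        for sample in samples:
            callset.add(GenotypeCall(
                sample=sample, site=site,
                alleles=_GENOTYPE_ALLELES[int(rng.binomial(2, 0.2))],
                platform=Platform.PANEL,
                call_rate=round(float(100.0 * rng.beta(a, b)), 1),
            ))
    return callset


def generate_targets(config: SimulationConfig) -> TargetIntervals:
    """Capture-target intervals placed so that ``on_target_fraction`` of
    sites fall inside an interval and the rest sit at varied distances
    (some within a 100-base padding, some far beyond)."""
    config.validate()
    sites, _ = generate_sites(config)
    rng = _stage_rng(config, _STAGE_TARGETS)
    triples: list[tuple[str, int, int]] = []
    for site in sites:
        pos = site.position
        if rng.random() < config.on_target_fraction:
            left = int(rng.integers(10, 120))
            right = int(rng.integers(10, 120))
            triples.append((site.contig, max(1, pos - left), pos + right))
        else:
            gap = int(rng.choice([5, 25, 60, 90, 150, 400, 1000]))
            length = int(rng.integers(80, 200))
            triples.append((site.contig, pos + gap, pos + gap + length))
    return TargetIntervals.from_intervals(triples)


@dataclass
class StudyData:
    """All artifacts of one simulated study."""

    config: SimulationConfig
    truth: Callset
    test: TestSimulation
    panel: Callset
    targets: TargetIntervals


def simulate_study(config: SimulationConfig) -> StudyData:
    """Run all generation stages in their frozen order."""
    config.validate()
    truth = generate_truth(config)
    test = simulate_test_callset(truth, config)
    panel = simulate_panel_callset(truth, config)
    targets = generate_targets(config)
    return StudyData(config=config, truth=truth, test=test, panel=panel, targets=targets)
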