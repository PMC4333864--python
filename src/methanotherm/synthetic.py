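"""Synthetic anaerobic-incubation experiments with known ground truth.

Emulates a temperature-ladder bottle incubation of anoxic wetland soil:

* cumulative CH4 follows a modified Gompertz curve whose maximal slope obeys a
  two-regime Arrhenius law (steep below a break temperature, shallow above)
  and whose lag shrinks exponentially with temperature;
* cumulative CO2 accumulates linearly from day 0 (no lag) with a
  single-regime Arrhenius rate;
* total methanogen abundance (mcrA copies) grows logistically toward a
  temperature-increasing carrying capacity, with a qPCR detection limit below
  which cells read "not detected";
* d13C-CH4 is a two-endmember mixture of aceticlastic and hydrogenotrophic
  CH4 whose hydrogenotrophic fraction f_h rises logistically with temperature;
* T-RFLP profiles and clone libraries are multinomial samples from a taxon
  table whose composition drifts with temperature and time (hydrogenotrophs
  outgrow aceticlastic methanogens when warm).

Every simulator is deterministic given (config, seed), and the returned
dataset carries the realized noise-free truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .isotope import IsotopeRecord, mixing_delta
from .kinetics import GasTimeSeries
from .thermo import BOLTZMANN_EV_PER_K, QpcrTable
from .community import CloneLibrary, TrflpProfile

import pandas as pd

PATHWAYS = ("aceticlastic", "hydrogenotrophic", "non-methanogen")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonSpec:
    """One archaeal taxon: pathway, predicted T-RF, and growth-vs-temperature rule.

    Growth rate is ``growth_rate_at_ref * exp(temp_slope * (T - ref_temperature_C))``
    per day; taxa sharing a ``trf_bp`` collide into a single T-RFLP peak.
    """

    name: str
    pathway: str
    trf_bp: int
    growth_rate_at_ref: float
    temp_slope: float = 0.0
    initial_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ScenarioError(f"pathway must be one of {PATHWAYS}, got {self.pathway!r}")
        if self.trf_bp < 1:
            raise ScenarioError("trf_bp must be >= 1")
        if self.growth_rate_at_ref < 0:
            raise ScenarioError("growth_rate_at_ref must be >= 0")

    def growth_rate(self, temperature_C: float, ref_temperature_C: float) -> float:
        return self.growth_rate_at_ref * math.exp(
            self.temp_slope * (temperature_C - ref_temperature_C)
        )


def default_taxa() -> list[TaxonSpec]:
    """Taxon table mirroring the archaeal community of a cold-fen soil.

    The 185-bp fragment is shared by the aceticlastic Methanosarcinaceae and
    the non-methanogenic crenarchaeotal group 1.1b; hydrogenotrophs carry the
    91-bp (Methanobacteriaceae, with the LDS cluster as a non-methanogen
    sharing that size) and 392-bp (Methanomicrobiaceae, Methanocellales)
    fragments. Hydrogenotrophs respond more steeply to warming.
    """
    return [
        TaxonSpec("Methanosarcinaceae", "aceticlastic", 185, 0.020, 0.02, 0.30),
        TaxonSpec("Crenarchaeota group 1.1b", "non-methanogen", 185, 0.000, 0.00, 0.42),
        TaxonSpec("Methanosaetaceae", "aceticlastic", 282, 0.010, 0.02, 0.04),
        TaxonSpec("Methanobacteriaceae", "hydrogenotrophic", 91, 0.060, 0.08, 0.06),
        TaxonSpec("LDS cluster", "non-methanogen", 91, 0.030, 0.05, 0.03),
        TaxonSpec("Methanomicrobiaceae", "hydrogenotrophic", 392, 0.050, 0.08, 0.04),
        TaxonSpec("Methanocellales", "hydrogenotrophic", 392, 0.050, 0.08, 0.03),
    ]


def _rare_taxa(n: int, total_fraction: float) -> list[TaxonSpec]:
    """A tail of rare non-methanogen taxa so clone libraries contain singletons
    and T-RFLP profiles carry a 'Diverse' residual."""
    if n <= 0:
        return []
    frac = total_fraction / n
    out = []
    for i in range(n):
        bp = 100 + 7 * i
        if bp in (91, 185, 282, 392):
            bp += 3
        out.append(
            TaxonSpec(f"rare-{i:02d}", "non-methanogen", bp, 0.0, 0.0, frac)
        )
    return out


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic incubation experiment.

    Rates are in arbitrary headspace units per day (activation-energy
    estimation is invariant to rate rescaling, so the unit is a convention);
    temperatures in degC; energies in eV; deltas in per mil vs VPDB; mcrA in
    1e6 copies per bottle.
    """

    temperatures_C: list[float] = field(default_factory=lambda: [10, 15, 20, 25, 30, 35])
    duration_days: float = 81.0
    sampling_days: list[float] = field(default_factory=lambda: [float(d) for d in range(0, 82, 3)])
    replicates: int = 3
    # CH4 Arrhenius law: steep E_low regime at and below T_break_C, E_high above
    E_low: float = 3.9
    E_high: float = 1.1
    T_break_C: float = 17.5
    E_co2: float = 0.6
    ch4_rate_at_ref: float = 11.884  # units/day at ref_temperature_C
    co2_rate_at_ref: float = 30.0
    ref_temperature_C: float = 35.0
    boltzmann_eV_per_K: float = BOLTZMANN_EV_PER_K
    # lag(T) = lag_ref * exp(-lag_k * (T - lag_ref_temperature_C))
    lag_ref_days: float = 10.0
    lag_ref_temperature_C: float = 30.0
    lag_k: float = 0.08
    amplitude_days: float = 20.0  # Gompertz amplitude = amplitude_days * p_max
    # mcrA logistic growth: carrying capacity blends a cold plateau and a warm
    # branch (log-linear in T each) across the community-shift temperature,
    # emulating the sharp 15->20 degC jump in observed total mcrA abundances
    mcra_n0: float = 0.01
    mcra_K_cold_at_10: float = 0.9
    mcra_K_cold_slope: float = 0.006  # per degC
    mcra_K_warm_at_35: float = 60.0
    mcra_K_warm_slope: float = 0.065  # per degC
    mcra_K_blend_midpoint_C: float = 17.5
    mcra_K_blend_width_C: float = 1.0
    mcra_r_at_ref: float = 0.25  # per day
    mcra_r_slope: float = 0.05  # per degC
    mcra_detection_limit: float = 0.1
    qpcr_days: list[float] = field(default_factory=lambda: [3.0, 24.0, 49.0, 65.0, 81.0])
    # isotopes
    delta_acetoclastic: float = -40.0
    delta_hydrogenotrophic: float = -80.0
    d13c_co2_base: float = -18.0
    d13c_co2_drift: float = 0.01  # per mil / day
    isotope_temperatures: list[float] = field(default_factory=lambda: [15.0, 25.0, 35.0])
    # f_h(T) = f_h_max / (1 + exp(-(T - f_h_midpoint_C)/f_h_width_C))
    f_h_max: float = 0.5
    f_h_midpoint_C: float = 20.0
    f_h_width_C: float = 3.0
    # community
    taxa: list[TaxonSpec] = field(default_factory=lambda: default_taxa() + _rare_taxa(20, 0.08))
    growth_ref_temperature_C: float = 25.0
    trflp_days: list[float] = field(default_factory=lambda: [0.0, 20.0, 49.0, 81.0])
    trflp_total_counts: int = 10000
    clone_library_size: int = 100
    library_temperatures: list[float] = field(default_factory=lambda: [15.0, 25.0, 35.0])
    library_day: float = 49.0
    # relative noise levels
    noise_gas: float = 0.05  # lognormal sigma on gas amounts
    noise_qpcr: float = 0.2  # lognormal sigma on per-replicate copies
    noise_delta_permil: float = 1.0  # additive Gaussian on deltas
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.temperatures_C
        if not t or any(b <= a for a, b in zip(t, t[1:])):
            raise ScenarioError("temperatures must be non-empty and strictly increasing")
        if self.duration_days <= 0:
            raise ScenarioError("duration must be positive")
        if min(self.E_low, self.E_high, self.E_co2) < 0:
            raise ScenarioError("activation energies must be >= 0")
        if self.replicates < 1:
            raise ScenarioError("need at least one replicate")
        if min(self.delta_acetoclastic, self.delta_hydrogenotrophic) <= -1000:
            raise ScenarioError("delta endmembers must exceed -1000 per mil")
        if min(self.noise_gas, self.noise_qpcr, self.noise_delta_permil) < 0:
            raise ScenarioError("noise levels must be >= 0")
        if not 0.0 <= self.f_h_max <= 1.0:
            raise ScenarioError("f_h_max must lie in [0, 1]")

    # -- ground-truth rules ------------------------------------------------

    def _x(self, temperature_C: float) -> float:
        return -1.0 / (self.boltzmann_eV_per_K * (temperature_C + 273.15))

    def ch4_rate(self, temperature_C: float) -> float:
        """Two-regime Arrhenius maximal CH4 rate, continuous at the break."""
        x = self._x(temperature_C)
        m_high = math.log(self.ch4_rate_at_ref) - self.E_high * self._x(self.ref_temperature_C)
        if temperature_C > self.T_break_C:
            return math.exp(self.E_high * x + m_high)
        x_b = self._x(self.T_break_C)
        m_low = m_high + (self.E_high - self.E_low) * x_b
        return math.exp(self.E_low * x + m_low)

    def co2_rate(self, temperature_C: float) -> float:
        m = math.log(self.co2_rate_at_ref) - self.E_co2 * self._x(self.ref_temperature_C)
        return math.exp(self.E_co2 * self._x(temperature_C) + m)

    def lag_days(self, temperature_C: float) -> float:
        return self.lag_ref_days * math.exp(
            -self.lag_k * (temperature_C - self.lag_ref_temperature_C)
        )

    def mcra_carrying_capacity(self, temperature_C: float) -> float:
        """Log-space blend of the cold plateau and warm branch of total mcrA."""
        ln_cold = math.log(self.mcra_K_cold_at_10) + self.mcra_K_cold_slope * (
            temperature_C - 10.0
        )
        ln_warm = math.log(self.mcra_K_warm_at_35) + self.mcra_K_warm_slope * (
            temperature_C - 35.0
        )
        w = 1.0 / (
            1.0
            + math.exp(
                -(temperature_C - self.mcra_K_blend_midpoint_C)
                / self.mcra_K_blend_width_C
            )
        )
        return math.exp((1.0 - w) * ln_cold + w * ln_warm)

    def f_h(self, temperature_C: float) -> float:
        return self.f_h_max / (
            1.0 + math.exp(-(temperature_C - self.f_h_midpoint_C) / self.f_h_width_C)
        )

    def taxon_fractions(self, temperature_C: float, day: float) -> dict[str, float]:
        """Noise-free community composition at one temperature and day."""
        weights = {}
        for tx in self.taxa:
            g = tx.growth_rate(temperature_C, self.growth_ref_temperature_C)
            weights[tx.name] = tx.initial_fraction * math.exp(g * day)
        total = sum(weights.values())
        return {k: v / total for k, v in weights.items()}


def build_default_scenario(**overrides) -> ScenarioConfig:
    """The default temperature-ladder experiment: 10-35 degC in 5-degC steps,
    81 days, triplicate bottles, two-regime CH4 / single-regime CO2."""
    return ScenarioConfig(**overrides)


def gompertz_cumulative(t: np.ndarray, amplitude: float, mu: float, lag: float) -> np.ndarray:
    """Modified Gompertz cumulative curve with maximal slope ``mu`` and lag
    ``lag`` (tangent through the inflection crosses zero at t = lag)."""
    t = np.asarray(t, dtype=float)
    if amplitude <= 0 or mu <= 0:
        return np.zeros_like(t)
    z = mu * math.e / amplitude * (lag - t) + 1.0
    return amplitude * np.exp(-np.exp(z))


def simulate_gas(config: ScenarioConfig, seed: int) -> list[GasTimeSeries]:
    """Cumulative CH4 (lagged Gompertz) and CO2 (lag-free linear) per bottle."""
    if config.duration_days <= 0 or not config.temperatures_C:
        raise ScenarioError("invalid config")
    rng = np.random.default_rng(seed)
    t = np.asarray(config.sampling_days, dtype=float)
    out = []
    for temp in config.temperatures_C:
        p = config.ch4_rate(temp)
        lag = config.lag_days(temp)
        amp = config.amplitude_days * p
        ch4_true = gompertz_cumulative(t, amp, p, lag)
        co2_true = config.co2_rate(temp) * t
        for rep in range(config.replicates):
            if config.noise_gas > 0:
                ch4 = ch4_true * np.exp(rng.normal(0.0, config.noise_gas, t.size))
                co2 = co2_true * np.exp(rng.normal(0.0, config.noise_gas, t.size))
            else:
                ch4, co2 = ch4_true.copy(), co2_true.copy()
            out.append(
                GasTimeSeries(
                    temperature_C=float(temp),
                    replicate=f"r{rep + 1}",
                    times=t.copy(),
                    ch4=ch4,
                    co2=co2,
                )
            )
    return out


def simulate_mcra(config: ScenarioConfig, seed: int) -> QpcrTable:
    """Logistic mcrA growth toward a temperature-increasing carrying capacity.

    Per-replicate lognormal noise; cells whose replicate mean falls below the
    detection limit are emitted as not-detected (NaN), never as zero.
    """
    rng = np.random.default_rng(seed)
    days = list(config.qpcr_days)
    means = pd.DataFrame(index=pd.Index(days, name="day"),
                         columns=[float(T) for T in config.temperatures_C], dtype=float)
    ses = means.copy()
    for temp in config.temperatures_C:
        k = config.mcra_carrying_capacity(temp)
        r = config.mcra_r_at_ref * math.exp(
            config.mcra_r_slope * (temp - config.ref_temperature_C)
        )
        n0 = config.mcra_n0
        for day in days:
            true = k / (1.0 + (k - n0) / n0 * math.exp(-r * day))
            if config.noise_qpcr > 0:
                reps = true * np.exp(rng.normal(0.0, config.noise_qpcr, config.replicates))
            else:
                reps = np.full(config.replicates, true)
            m = float(np.mean(reps))
            se = (
                float(np.std(reps, ddof=1) / math.sqrt(len(reps)))
                if len(reps) > 1
                else 0.0
            )
            if m < config.mcra_detection_limit:
                m, se = math.nan, math.nan
            means.loc[day, float(temp)] = m
            ses.loc[day, float(temp)] = se
    return QpcrTable(means=means, ses=ses)


def simulate_isotopes(config: ScenarioConfig, seed: int) -> list[IsotopeRecord]:
    """d13C-CH4 as a two-endmember mixture with f_h set by temperature;
    d13C-CO2 with a small linear drift."""
    rng = np.random.default_rng(seed)
    out = []
    for temp in config.isotope_temperatures:
        f_h = config.f_h(temp)
        if not 0.0 <= f_h <= 1.0:
            raise ScenarioError(f"f_h out of [0,1] at {temp} degC: {f_h}")
        base = mixing_delta(f_h, config.delta_hydrogenotrophic, config.delta_acetoclastic)
        for day in config.sampling_days:
            if day == 0:
                continue  # no headspace CH4 to measure yet
            d_ch4 = base + (rng.normal(0.0, config.noise_delta_permil) if config.noise_delta_permil > 0 else 0.0)
            d_co2 = config.d13c_co2_base + config.d13c_co2_drift * day + (
                rng.normal(0.0, config.noise_delta_permil) if config.noise_delta_permil > 0 else 0.0
            )
            out.append(
                IsotopeRecord(
                    temperature_C=float(temp), day=float(day),
                    d13c_ch4=float(d_ch4), d13c_co2=float(d_co2),
                )
            )
    return out


def simulate_community(
    config: ScenarioConfig, seed: int
) -> tuple[list[TrflpProfile], list[CloneLibrary]]:
    """Multinomial T-RFLP profiles and clone libraries from the taxon table.

    Peak heights of taxa sharing a fragment size are summed into one peak;
    clone libraries are drawn at ``library_day`` for ``library_temperatures``
    with ``clone_library_size`` clones each (one OTU per taxon).
    """
    rng = np.random.default_rng(seed)
    names = [tx.name for tx in config.taxa]
    trfs = {tx.name: tx.trf_bp for tx in config.taxa}
    profiles = []
    for temp in config.temperatures_C:
        for day in config.trflp_days:
            fr = config.taxon_fractions(temp, day)
            p = np.array([fr[n] for n in names])
            for rep in range(config.replicates):
                counts = rng.multinomial(config.trflp_total_counts, p)
                by_bp: dict[int, float] = {}
                for name, c in zip(names, counts):
                    if c > 0:
                        by_bp[trfs[name]] = by_bp.get(trfs[name], 0.0) + float(c)
                bps = sorted(by_bp)
                profiles.append(
                    TrflpProfile(
                        temperature_C=float(temp), day=float(day),
                        replicate=f"r{rep + 1}",
                        trf_bp=bps, heights=[by_bp[b] for b in bps],
                    )
                )
    libraries = []
    for temp in config.library_temperatures:
        fr = config.taxon_fractions(temp, config.library_day)
        p = np.array([fr[n] for n in names])
        counts = rng.multinomial(config.clone_library_size, p)
        libraries.append(
            CloneLibrary(
                label=f"{temp:g}C_day{config.library_day:g}",
                otu_counts=[int(c) for c in counts if c > 0],
            )
        )
    return profiles, libraries


def synthesize_amplicons(
    taxa: Sequence[TaxonSpec],
    length: int = 800,
    seed: int = 0,
    site: str = "TCGA",
    cut_offset: int = 1,
) -> dict[str, str]:
    """Synthetic 16S amplicon stand-ins whose labeled-end TaqI fragment equals
    each taxon's trf_bp.

    Sequences are returned in the deposited (forward) orientation; reading
    them 5'->3' from the labeled reverse-primer end (reverse complement) and
    cutting at the first TaqI site yields exactly ``trf_bp``. These are
    synthetic stand-ins for real clone sequences, with the fragment structure
    as the only designed feature.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = {}
    for tx in taxa:
        if tx.trf_bp + len(site) > length:
            raise ScenarioError(f"trf_bp {tx.trf_bp} too long for amplicon length {length}")
        while True:
            # labeled orientation: [prefix of trf_bp - cut_offset bases][site][suffix]
            prefix = "".join(rng.choice(bases, size=tx.trf_bp - cut_offset))
            suffix = "".join(rng.choice(bases, size=length - tx.trf_bp + cut_offset - len(site)))
            labeled = prefix + site + suffix
            if labeled.find(site) == tx.trf_bp - cut_offset:
                break
        out[tx.name] = str(Seq(labeled).reverse_complement())
    return out


@dataclass
class SyntheticDataset:
    """One complete simulated experiment plus its generating truth."""

    config: ScenarioConfig
    gas: list[GasTimeSeries]
    qpcr: QpcrTable
    isotopes: list[IsotopeRecord]
    profiles: list[TrflpProfile]
    libraries: list[CloneLibrary]
    truth: dict

    def truth_json(self) -> str:
        def _default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps({"config": dataclasses.asdict(self.config), "truth": self.truth},
                          default=_default, indent=2)


def simulate_dataset(config: ScenarioConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate every observable layer of one experiment deterministically.

    Child streams for the four observable layers are derived from the one seed
    so layers are independent yet reproducible.
    """
    config = config or build_default_scenario()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_gas, s_mcra, s_iso, s_comm = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    gas = simulate_gas(config, s_gas)
    qpcr = simulate_mcra(config, s_mcra)
    isotopes = simulate_isotopes(config, s_iso)
    profiles, libraries = simulate_community(config, s_comm)
    truth = {
        "ch4_rate": {f"{T:g}": config.ch4_rate(T) for T in config.temperatures_C},
        "co2_rate": {f"{T:g}": config.co2_rate(T) for T in config.temperatures_C},
        "lag_days": {f"{T:g}": config.lag_days(T) for T in config.temperatures_C},
        "f_h": {f"{T:g}": config.f_h(T) for T in config.isotope_temperatures},
        "fractions": {
            f"{T:g}": {
                f"{d:g}": config.taxon_fractions(T, d) for d in config.trflp_days
            }
            for T in config.temperatures_C
        },
    }
    return SyntheticDataset(
        config=config, gas=gas, qpcr=qpcr, isotopes=isotopes,
        profiles=profiles, libraries=libraries, truth=truth,
    )
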