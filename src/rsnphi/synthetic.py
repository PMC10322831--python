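"""Synthetic cohorts of coupled binary network time-series.

Real resting-state networks have unknown dynamics; to make every stage of
the pipeline testable against ground truth, this module generates cohorts
from an *explicit* state-by-state transition probability matrix per
network and condition.  The generative TPM mixes

* an independent part, where each node follows its own two-state chain
  (persistence and turn-on rates drawn per node), and
* a synchronizing part, where the whole network jumps to all-ON with a
  probability given by the current fraction of active nodes (and to
  all-OFF otherwise),

weighted by a coupling strength ``c`` in [0, 1].  At ``c = 0`` the TPM
factorizes over nodes (zero conditional-independence distance, zero
integration); increasing ``c`` introduces both cross-node next-state
correlation and strong temporal structure, which is what the integrated
information and causal-density metrics are designed to detect and what
temporal shuffling destroys.

The default cohort emulates the structure of a propofol-sedation study:
17 subjects x 4 conditions (Awake, Mild, Deep, Recovery) x 11 named
networks of 5 regions, 245 time points per subject at TR = 2 s.  Sedation
acts multiplicatively on coupling through a per-condition modulation
profile ([1, 0.7, 0.3, 1] by default: attenuated in deep sedation,
restored in recovery), scaled per network by a sensitivity in [0, 1] so
that some networks (e.g. the frontoparietal and dorsal-attention
analogues) track the profile strongly while sensory analogues barely
respond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryTimeSeries
from .states import StateByNodeTPM, StateByStateTPM, all_states, sbn_to_sbs

DEFAULT_CONDITIONS = ("Awake", "Mild", "Deep", "Recovery")
DEFAULT_PROFILE = (1.0, 0.7, 0.3, 1.0)

#: label -> (baseline coupling, sedation sensitivity).  Couplings give the
#: sensorimotor analogues the largest baseline integration and the
#: default-mode analogue the smallest; sensitivities make the
#: frontoparietal and dorsal-attention analogues track the sedation
#: profile most strongly.
DEFAULT_NETWORKS: dict[str, tuple[float, float]] = {
    "FPN": (0.65, 1.0),
    "DAN": (0.60, 1.0),
    "DMN": (0.35, 0.50),
    "RS": (0.55, 0.30),
    "VAN": (0.55, 0.30),
    "CO": (0.60, 0.35),
    "CP": (0.58, 0.35),
    "SMH": (0.75, 0.15),
    "SMM": (0.80, 0.10),
    "VIS": (0.62, 0.20),
    "AUD": (0.58, 0.25),
}


def _seed_for(*parts: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(parts)))


@dataclass
class GroundTruthNetwork:
    """A generative law for one network: an explicit state-by-state TPM."""

    n_nodes: int
    tpm: StateByStateTPM
    coupling_strength: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.tpm.probs.shape[0] != 2**self.n_nodes:
            raise ValueError("TPM size inconsistent with n_nodes")


def make_coupled_tpm(n_nodes: int, coupling_strength: float,
                     seed: int, sync_floor: float = 0.1) -> StateByStateTPM:
    """Generative state-by-state TPM with tunable inter-node coupling.

    ``coupling_strength = 0`` yields a product of independent per-node
    chains (the TPM factorizes).  ``coupling_strength = 1`` yields a pure
    synchronizing rule in which all nodes jump together.  ``sync_floor``
    keeps the synchronizing kernel away from determinism so every state
    retains positive probability mass.
    """
    if not 2 <= n_nodes <= 6:
        raise ValueError("n_nodes must lie in [2, 6]")
    if not 0.0 <= coupling_strength <= 1.0:
        raise ValueError("coupling_strength must lie in [0, 1]")
    rng = _seed_for(seed)
    stay_on = rng.uniform(0.6, 0.9, size=n_nodes)    # P(on | own bit on)
    turn_on = rng.uniform(0.1, 0.4, size=n_nodes)    # P(on | own bit off)

    states = all_states(n_nodes)                     # (2**N, N)
    p_on = np.where(states == 1, stay_on, turn_on)   # (2**N, N) per-node
    independent = sbn_to_sbs(StateByNodeTPM(p_on)).probs

    q = sync_floor + (1 - 2 * sync_floor) * states.mean(axis=1)
    sync = np.zeros_like(independent)
    sync[:, -1] = q                                  # all-ON state
    sync[:, 0] = 1.0 - q                             # all-OFF state

    probs = (1 - coupling_strength) * independent + coupling_strength * sync
    return StateByStateTPM(probs)


def simulate_binary_series(net: GroundTruthNetwork, n_timepoints: int,
                           seed: int, region_labels: list[str] | None = None
                           ) -> BinaryTimeSeries:
    """Sample a Markov chain from the network's TPM.

    The initial state is uniform over all ``2**N`` states; identical seeds
    give identical series.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = _seed_for(seed)
    cdf = np.cumsum(net.tpm.probs, axis=1)
    cdf[:, -1] = 1.0
    idx = np.empty(n_timepoints, dtype=np.int64)
    idx[0] = rng.integers(0, 2**net.n_nodes)
    u = rng.random(n_timepoints - 1)
    for t in range(1, n_timepoints):
        idx[t] = np.searchsorted(cdf[idx[t - 1]], u[t - 1], side="right")
    values = (idx[:, None] >> np.arange(net.n_nodes)) & 1
    if region_labels is None:
        region_labels = [f"r{k}" for k in range(net.n_nodes)]
    return BinaryTimeSeries(values, region_labels)


def simulate_bold_like(net: GroundTruthNetwork, n_timepoints: int,
                       tr_seconds: float = 2.0, seed: int = 0,
                       ar_coeff: float = 0.5, noise_sd: float = 1.0,
                       drift_amplitude: float = 0.0,
                       drift_hz: float = 0.003) -> np.ndarray:
    """Continuous BOLD-like precursors: coupled AR(1) + noise + slow drift.

    Each channel follows ``x_t = a x_{t-1} + (c/(N-1)) sum_{j!=i} x_{j,t-1}
    / 2 + noise`` with coupling ``c`` from the network, plus an optional
    slow sinusoidal drift (below the band-pass) and linear trend, so the
    detrend/filter/binarize chain has real work to do.  Returns a plain
    time x region float array.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    rng = _seed_for(seed)
    n = net.n_nodes
    c = net.coupling_strength
    coupling = np.full((n, n), 0.5 * c / max(n - 1, 1))
    np.fill_diagonal(coupling, ar_coeff)
    x = np.zeros((n_timepoints, n))
    x[0] = rng.standard_normal(n)
    noise = noise_sd * rng.standard_normal((n_timepoints, n))
    for t in range(1, n_timepoints):
        x[t] = coupling @ x[t - 1] + noise[t]
    if drift_amplitude:
        tsec = np.arange(n_timepoints) * tr_seconds
        phase = rng.uniform(0, 2 * np.pi, size=n)
        drift = drift_amplitude * (
            np.sin(2 * np.pi * drift_hz * tsec[:, None] + phase)
            + (tsec / tsec[-1])[:, None]
        )
        x = x + drift
    return x


@dataclass
class SyntheticCohort:
    """Specification of a synthetic cohort (who, how long, which dynamics)."""

    subjects: int = 17
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_timepoints: int = 245
    n_nodes: int = 5
    networks: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NETWORKS))
    modulation_profile: tuple[float, ...] = DEFAULT_PROFILE
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subjects < 1 or self.n_timepoints < 2:
            raise ValueError("need >= 1 subject and >= 2 time points")
        if len(self.modulation_profile) != len(self.conditions):
            raise ValueError("modulation_profile must match conditions")
        for label, (c, s) in self.networks.items():
            if not (0 <= c <= 1 and 0 <= s <= 1):
                raise ValueError(f"coupling/sensitivity out of [0,1] for {label}")

    def effective_coupling(self, label: str, condition: str) -> float:
        """Coupling after sedation modulation, scaled by network sensitivity."""
        base, sens = self.networks[label]
        mult = self.modulation_profile[self.conditions.index(condition)]
        return base * (1.0 - sens * (1.0 - mult))

    @property
    def modulated_networks(self) -> list[str]:
        """Networks whose sensitivity is above the cohort median."""
        sens = sorted(s for _, s in self.networks.values())
        median = sens[len(sens) // 2]
        return [l for l, (_, s) in self.networks.items() if s > median]


@dataclass
class CohortData:
    """A generated cohort plus its ground-truth generative laws."""

    spec: SyntheticCohort
    series: dict[tuple[str, str, int], BinaryTimeSeries]
    generative: dict[tuple[str, str], GroundTruthNetwork]

    def subject_series(self, network: str, condition: str
                       ) -> list[BinaryTimeSeries]:
        return [self.series[(network, condition, i)]
                for i in range(self.spec.subjects)]


def generate_cohort(spec: SyntheticCohort) -> CohortData:
    """Generate every (network, condition, subject) series of the cohort.

    The per-network node parameters are drawn once from the cohort seed,
    so conditions differ *only* through the modulated coupling; the
    generative TPM for each (network, condition) is recorded for
    ground-truth checks.
    """
    series: dict[tuple[str, str, int], BinaryTimeSeries] = {}
    generative: dict[tuple[str, str], GroundTruthNetwork] = {}
    labels = [f"r{k}" for k in range(spec.n_nodes)]
    for ni, name in enumerate(spec.networks):
        for ci, cond in enumerate(spec.conditions):
            c_eff = spec.effective_coupling(name, cond)
            tpm = make_coupled_tpm(spec.n_nodes, c_eff,
                                   seed=hash_seed(spec.seed, ni))
            net = GroundTruthNetwork(spec.n_nodes, tpm, c_eff, label=name)
            generative[(name, cond)] = net
            for si in range(spec.subjects):
                rng_seed = hash_seed(spec.seed, ni, ci, si)
                series[(name, cond, si)] = simulate_binary_series(
                    net, spec.n_timepoints, seed=rng_seed,
                    region_labels=labels)
    return CohortData(spec=spec, series=series, generative=generative)


def hash_seed(*parts: int) -> int:
    """Deterministically fold several integers into one sub-2**31 seed."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
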