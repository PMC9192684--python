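"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one input of the analysis chain at the scale of
a 155-cow feed-efficiency trial with a 5-vs-5 adipose proteome
sub-study:

- :func:`simulate_herd` — daily performance records where each cow's
  intake is her NRC-predicted intake plus a persistent per-cow
  efficiency offset (the ground truth RFI) plus daily noise.
- :func:`simulate_peptides` — a peptide intensity table for ~2,260
  proteins with 1–30 peptides each, log-normal intensities, per-sample
  TIC variation, a spiked differential subset (default 43 up / 58 down,
  |FC| log-uniform in [1.5, 80]) and intensity-dependent missingness.
- :func:`simulate_annotations` — random GMT terms plus one designated
  term preferentially drawn from the spiked proteins.
- :func:`simulate_ct` — qPCR Ct tables consistent with configured true
  expression ratios under perfect doubling plus cycle noise.

All generators are pure functions of their config (seed included) and
return ``(data, truth)``; truth frames are for verification only and are
never consumed by the pipeline under test. Missingness is
intensity-dependent (left-censored-like) because label-free MS
preferentially drops low-abundance peptides; set the rate to 0 for
clean oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from efficow.enrichment import AnnotationSet
from efficow.feed_efficiency import EfficiencyParams, compute_ecm, predict_dmi

__all__ = [
    "HerdSimConfig",
    "ProteomeSimConfig",
    "QpcrSimConfig",
    "simulate_herd",
    "simulate_peptides",
    "simulate_annotations",
    "simulate_ct",
]


@dataclass(frozen=True)
class HerdSimConfig:
    """Herd generator settings (defaults mirror a mid-lactation trial).

    ``efficiency_offset_sd`` is the SD of the persistent per-cow intake
    offset above/below predicted (kg/d) — the true RFI signal;
    ``daily_noise_sd`` is day-to-day intake noise around it.
    """

    n_cows: int = 155
    window_days: int = 35
    dim_min: int = 80
    dim_max: int = 140
    bw_mean: float = 590.0
    bw_sd: float = 35.0
    milk_mean: float = 47.0
    milk_sd: float = 5.0
    fat_pct: float = 3.05
    protein_pct: float = 2.98
    lactose_pct: float = 4.91
    component_jitter_sd: float = 0.08
    milk_daily_sd: float = 1.5
    efficiency_offset_sd: float = 2.0
    daily_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 10:
            raise ValueError("n_cows must be >= 10")
        for name in ("bw_sd", "milk_sd", "component_jitter_sd",
                     "milk_daily_sd", "efficiency_offset_sd", "daily_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.dim_min <= self.dim_max:
            raise ValueError("need 0 < dim_min <= dim_max")


def simulate_herd(config: HerdSimConfig = HerdSimConfig(),
                  params: EfficiencyParams = EfficiencyParams(),
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate daily performance records plus per-cow truth offsets.

    Daily DMI = predicted DMI (from that day's simulated ECM, BW, DIM)
    + the cow's persistent efficiency offset + daily noise; an
    unbiased scorer should therefore recover RFI ≈ offset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cows
    cow_ids = [f"cow{idx:04d}" for idx in range(1, n + 1)]
    dim0 = rng.integers(config.dim_min, config.dim_max + 1, size=n)
    bw0 = rng.normal(config.bw_mean, config.bw_sd, size=n).clip(min=350)
    milk_base = rng.normal(config.milk_mean, config.milk_sd, size=n).clip(min=10)
    fat = rng.normal(config.fat_pct, config.component_jitter_sd, n).clip(min=1)
    prot = rng.normal(config.protein_pct, config.component_jitter_sd, n).clip(min=1)
    lact = rng.normal(config.lactose_pct, config.component_jitter_sd, n).clip(min=1)
    offsets = rng.normal(0.0, config.efficiency_offset_sd, size=n)

    frames = []
    for i in range(n):
        days = np.arange(1, config.window_days + 1)
        dim = dim0[i] + days - 1
        bw = bw0[i] + 0.1 * (days - 1)  # mild within-window gain
        milk = (milk_base[i]
                + rng.normal(0.0, config.milk_daily_sd, config.window_days)
                ).clip(min=0)
        ecm = compute_ecm(milk, fat[i], prot[i], lact[i], params)
        pred = predict_dmi(ecm, bw, dim, params)
        dmi = (pred + offsets[i]
               + rng.normal(0.0, config.daily_noise_sd, config.window_days)
               ).clip(min=0)
        frames.append(pd.DataFrame({
            "cow_id": cow_ids[i], "day": days, "dim": dim, "bw_kg": bw,
            "dmi_kg": dmi, "milk_kg": milk, "fat_pct": fat[i],
            "protein_pct": prot[i], "lactose_pct": lact[i],
        }))
    truth = pd.DataFrame({"cow_id": cow_ids, "true_offset": offsets})
    return pd.concat(frames, ignore_index=True), truth


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Peptide-table generator settings.

    Scale defaults match a quantified adipose proteome: ~2,260 proteins,
    geometric peptides-per-protein (mean 8, truncated to 1–30), 5 vs 5
    samples, 43 up- and 58 down-spiked proteins with |FC| log-uniform in
    [1.5, 80]. ``within_cv`` is the biological+technical CV of protein
    abundance within a group on the raw scale; ``missing_rate`` is the
    overall fraction of intensities censored, biased toward low values.
    """

    n_proteins: int = 2260
    peptides_mean: float = 8.0
    peptides_max: int = 30
    n_case: int = 5
    n_ctrl: int = 5
    case_label: str = "HEF"
    ctrl_label: str = "LEF"
    log2_abundance_mean: float = 20.0
    log2_abundance_sd: float = 2.0
    peptide_factor_log2_sd: float = 1.5
    tic_log2_sd: float = 0.35
    n_spike_up: int = 43
    n_spike_down: int = 58
    fc_min: float = 1.5
    fc_max: float = 80.0
    within_cv: float = 0.20
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spike_up + self.n_spike_down > self.n_proteins:
            raise ValueError("spike counts exceed n_proteins")
        if self.fc_min < 1 or self.fc_max < self.fc_min:
            raise ValueError("need 1 <= fc_min <= fc_max")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.within_cv < 0:
            raise ValueError("within_cv must be >= 0")


def _cv_to_log2_sd(cv: float) -> float:
    # SD on log2 scale of a log-normal with raw-scale CV
    return float(np.sqrt(np.log(1.0 + cv ** 2)) / np.log(2.0))


def simulate_peptides(config: ProteomeSimConfig = ProteomeSimConfig(),
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a peptide intensity table, sample sheet and protein truth.

    Returns ``(peptides, samples, truth)``. ``peptides`` has peptide_id,
    protein_id and one intensity column per sample (NaN = missing);
    ``samples`` maps sample_id → group; ``truth`` holds each protein's
    spike flag and signed true fold change (case over control; +1 for
    nulls). True FCs act at the protein level, so all of a protein's
    peptides shift together — matching the rollup's assumption.
    """
    rng = np.random.default_rng(config.seed)
    nP = config.n_proteins
    protein_ids = np.array([f"P{idx:05d}" for idx in range(1, nP + 1)])

    # geometric peptides-per-protein, truncated to [1, peptides_max]
    n_pep = rng.geometric(1.0 / config.peptides_mean, size=nP)
    n_pep = np.clip(n_pep, 1, config.peptides_max)

    spike_idx = rng.choice(nP, size=config.n_spike_up + config.n_spike_down,
                           replace=False)
    up_idx = spike_idx[:config.n_spike_up]
    down_idx = spike_idx[config.n_spike_up:]
    log2fc = np.zeros(nP)
    lo, hi = np.log2(config.fc_min), np.log2(config.fc_max)
    log2fc[up_idx] = rng.uniform(lo, hi, size=config.n_spike_up)
    log2fc[down_idx] = -rng.uniform(lo, hi, size=config.n_spike_down)

    sample_ids = ([f"{config.case_label}{j+1}" for j in range(config.n_case)]
                  + [f"{config.ctrl_label}{j+1}" for j in range(config.n_ctrl)])
    groups = ([config.case_label] * config.n_case
              + [config.ctrl_label] * config.n_ctrl)
    n_samp = len(sample_ids)
    is_case = np.array([g == config.case_label for g in groups])

    base = rng.normal(config.log2_abundance_mean, config.log2_abundance_sd, nP)
    tic_shift = rng.normal(0.0, config.tic_log2_sd, n_samp)
    within_sd = _cv_to_log2_sd(config.within_cv)
    # protein-level sample values on log2 scale (biological variation shared
    # by all of a protein's peptides)
    prot_log2 = (base[:, None]
                 + np.where(is_case[None, :], log2fc[:, None] / 2, -log2fc[:, None] / 2)
                 + rng.normal(0.0, within_sd, size=(nP, n_samp)))

    pep_protein = np.repeat(np.arange(nP), n_pep)
    n_rows = pep_protein.size
    pep_factor = rng.normal(0.0, config.peptide_factor_log2_sd, n_rows)
    noise = rng.normal(0.0, within_sd / 2, size=(n_rows, n_samp))  # technical
    log2_int = (prot_log2[pep_protein, :] + pep_factor[:, None]
                + tic_shift[None, :] + noise)
    intensity = np.power(2.0, log2_int)

    if config.missing_rate > 0:
        # left-censored-like: miss probability decreases with global rank
        q = stats_rankdata(log2_int.ravel()).reshape(log2_int.shape)
        p_miss = np.clip(2.0 * config.missing_rate * (1.0 - q), 0.0, 1.0)
        mask = rng.random(size=log2_int.shape) < p_miss
        # keep every sample and every peptide at least partially observed
        intensity[mask] = np.nan
        all_nan_rows = np.isnan(intensity).all(axis=1)
        intensity[all_nan_rows, 0] = np.power(2.0, log2_int[all_nan_rows, 0])

    pep_ids = [f"pep{idx:06d}" for idx in range(1, n_rows + 1)]
    peptides = pd.DataFrame(intensity, columns=sample_ids)
    peptides.insert(0, "protein_id", protein_ids[pep_protein])
    peptides.insert(0, "peptide_id", pep_ids)

    samples = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    spiked = np.zeros(nP, dtype=bool)
    spiked[spike_idx] = True
    ratio = np.power(2.0, log2fc)
    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "spiked": spiked,
        "true_log2fc": log2fc,
        "true_fc_signed": np.where(ratio >= 1, ratio, -1.0 / ratio),
    })
    return peptides, samples, truth


def stats_rankdata(x: np.ndarray) -> np.ndarray:
    """Ranks scaled to (0, 1); ties broken by position for determinism."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, x.size + 1)
    return ranks / (x.size + 1)


def simulate_annotations(protein_ids, spiked_ids, n_terms: int = 20,
                         term_size: int = 50, enrichment_odds: float = 8.0,
                         seed: int = 0,
                         ) -> tuple[list[AnnotationSet], dict]:
    """Random GMT terms with one designated spike-enriched term.

    Members of the designated term (``term_id`` ``"T0001"``) are sampled
    with ``enrichment_odds``-fold higher weight on spiked proteins; all
    other terms sample uniformly. ``enrichment_odds = 1`` makes the
    designated term null like the rest. Returns the annotation list and
    a truth dict naming the enriched term.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if enrichment_odds < 1:
        raise ValueError("enrichment_odds must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.asarray(sorted(map(str, protein_ids)))
    spiked = set(map(str, spiked_ids))
    size = min(term_size, universe.size)
    weights = np.where(np.isin(universe, list(spiked)), enrichment_odds, 1.0)
    weights = weights / weights.sum()
    sets = []
    for t in range(1, n_terms + 1):
        term_id = f"T{t:04d}"
        if t == 1:
            members = rng.choice(universe, size=size, replace=False, p=weights)
        else:
            members = rng.choice(universe, size=size, replace=False)
        sets.append(AnnotationSet(term_id, f"synthetic term {t}",
                                  frozenset(members.tolist())))
    return sets, {"enriched_term": "T0001", "odds": enrichment_odds}


@dataclass(frozen=True)
class QpcrSimConfig:
    """Ct-table generator settings.

    ``true_ratios`` are case/control expression ratios per target gene;
    ``reference_sds`` give each candidate housekeeping gene's Ct
    stability (SD in cycles) — the most stable one should win reference
    selection. ``ct_noise_sd`` is per-well cycle noise; ``sample_shift_sd``
    models loading differences that the reference gene must cancel.
    """

    true_ratios: dict = field(default_factory=lambda: {
        "RBM39": 0.37, "ITGAV": 0.78, "STAT2": 1.03, "DDX39A": 0.77,
    })
    reference_sds: dict = field(default_factory=lambda: {
        "GAPDH": 0.10, "UXT": 0.45, "BRPS2": 0.60, "EIF4E": 0.50, "ACTB": 0.35,
    })
    n_case: int = 5
    n_ctrl: int = 5
    case_label: str = "HEF"
    ctrl_label: str = "LEF"
    ct_noise_sd: float = 0.2
    sample_shift_sd: float = 0.3
    target_base_ct: float = 24.0
    reference_base_ct: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for g, r in self.true_ratios.items():
            if r <= 0:
                raise ValueError(f"true ratio for {g} must be > 0")


def simulate_ct(config: QpcrSimConfig = QpcrSimConfig(),
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format Ct table plus per-gene truth ratios.

    Under perfect doubling a case/control ratio r lowers the case Ct by
    log2(r) cycles. Per-sample loading shifts move every gene of a
    sample together and cancel in ΔCt.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = ([f"{config.case_label}{j+1}" for j in range(config.n_case)]
                  + [f"{config.ctrl_label}{j+1}" for j in range(config.n_ctrl)])
    groups = ([config.case_label] * config.n_case
              + [config.ctrl_label] * config.n_ctrl)
    shifts = rng.normal(0.0, config.sample_shift_sd, len(sample_ids))
    rows = []
    for s, (sample, group, shift) in enumerate(zip(sample_ids, groups, shifts)):
        for gene, ref_sd in config.reference_sds.items():
            ct = (config.reference_base_ct + shift
                  + rng.normal(0.0, ref_sd))
            rows.append({"sample_id": sample, "group": group,
                         "gene": gene, "ct": ct})
        for gene, ratio in config.true_ratios.items():
            effect = -np.log2(ratio) if group == config.case_label else 0.0
            ct = (config.target_base_ct + shift + effect
                  + rng.normal(0.0, config.ct_noise_sd))
            rows.append({"sample_id": sample, "group": group,
                         "gene": gene, "ct": ct})
    truth = pd.DataFrame({
        "gene": list(config.true_ratios),
        "true_ratio": [config.true_ratios[g] for g in config.true_ratios],
    })
    return pd.DataFrame(rows), truth
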