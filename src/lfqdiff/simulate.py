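"""Synthetic peptide-XIC experiments with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: log-normal peptide intensities, large per-peptide ionization
offsets, per-replicate location shifts, an injected condition effect for a
chosen fraction of features, features observed in only one condition,
sporadic outlier observations and missing values.

Generative model (log2 scale), for feature ``f``, peptide ``p``,
biological replicate ``r`` of condition ``c``, technical replicate ``t``::

    log2 x = B_f + P_p + R_{c,r} + Delta_f * 1[c == condition_b]
             + eps_{f,p,c,r} + tau_{f,p,c,r,t}

with ``B_f ~ N(baseline_log2_mean, baseline_log2_sd)``, ``P_p ~ N(0,
sigma_peptide)``, ``R ~ N(0, sigma_rep)`` shared by every observation of a
replicate, ``eps ~ N(0, sigma_noise)`` and ``tau ~ N(0, sigma_tech)``.
``Delta_f`` equals ``log2fc_changed`` for the changed features and 0
otherwise. Condition-specific features have every observation of the other
condition removed. With probability ``outlier_rate`` an observation is
shifted by ``outlier_shift`` log2 units; observations are then deleted
with probability ``missing_rate_base`` (optionally intensity-dependent).
Fractionated designs split each intensity across one or two randomly
chosen fractions with proportions summing to one on the linear scale, so
summing fractions recovers the pre-split value.

One RNG stream keyed by ``seed`` is consumed in a fixed, documented block
order (features -> peptides -> replicate effects -> observation noise ->
outliers -> missingness -> fractions), so the same seed always reproduces
the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import ConfigError, Design, QuantTable, Stage

__all__ = [
    "TruthParams",
    "SimulationTruth",
    "make_builtin_designs",
    "simulate_experiment",
    "fixture_toy_table",
]


@dataclass
class TruthParams:
    """Ground-truth parameters of one simulated experiment.

    Scale parameters are in log2 units. Defaults describe a realistic
    label-free screen: ~1% of features truly changed (substrate screens of
    this kind report candidate rates of 0.6–1.3%), 4-fold injected effects,
    biological replicate scatter of 0.3 and residual peptide-level noise of
    0.5 log2 units, peptide ionization offsets of SD 1 (between-peptide
    variance dominates real LFQ data), ~1% outlier observations and 10%
    missing observations.
    """

    n_features: int = 1000
    peptides_per_feature: tuple[int, int] = (2, 8)
    frac_changed: float = 0.01
    log2fc_changed: float = 2.0
    frac_specific_a: float = 0.005
    frac_specific_b: float = 0.005
    sigma_rep: float = 0.3
    sigma_noise: float = 0.5
    sigma_tech: float = 0.2
    sigma_peptide: float = 1.0
    outlier_rate: float = 0.01
    outlier_shift: float = 4.0
    missing_rate_base: float = 0.10
    missing_intensity_beta: float = 0.0
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peptides_per_feature
        if not (1 <= lo <= hi):
            raise ConfigError("peptides_per_feature must satisfy 1 <= min <= max")
        if self.n_features < 1:
            raise ConfigError("n_features must be positive")
        for attr in (
            "frac_changed",
            "frac_specific_a",
            "frac_specific_b",
            "outlier_rate",
            "missing_rate_base",
        ):
            if not 0 <= getattr(self, attr) <= 1:
                raise ConfigError(f"{attr} must be in [0, 1]")
        if self.frac_changed + self.frac_specific_a + self.frac_specific_b > 1:
            raise ConfigError(
                "frac_changed + frac_specific_a + frac_specific_b must be <= 1"
            )
        for attr in (
            "sigma_rep",
            "sigma_noise",
            "sigma_tech",
            "sigma_peptide",
            "baseline_log2_sd",
        ):
            if getattr(self, attr) < 0:
                raise ConfigError(f"{attr} must be >= 0")
        if self.missing_intensity_beta < 0:
            raise ConfigError("missing_intensity_beta must be >= 0")


@dataclass
class SimulationTruth:
    """Per-feature ground truth of one simulated experiment.

    ``features`` has one row per feature: ``feature_id`` (site key for
    site-level designs), ``protein_id``, ``true_log2fc`` (NaN for
    condition-specific features, whose fold change is undefined) and
    ``specific_flag`` (``none`` / ``a_only`` / ``b_only``).
    """

    features: pd.DataFrame
    outlier_observations: list[tuple] = field(default_factory=list)
    seed: int = 0

    @property
    def changed_ids(self) -> list[str]:
        f = self.features
        mask = (f["specific_flag"] == "none") & (f["true_log2fc"] != 0.0)
        return f.loc[mask, "feature_id"].tolist()

    @property
    def null_ids(self) -> list[str]:
        f = self.features
        mask = (f["specific_flag"] == "none") & (f["true_log2fc"] == 0.0)
        return f.loc[mask, "feature_id"].tolist()


def make_builtin_designs() -> dict[str, Design]:
    """The three built-in experimental designs.

    * ``proteome`` — whole proteome, parental (n=3) vs KO (n=6), six
      high-pH fractions per replicate, protein level.
    * ``digly`` — diGly-remnant ubiquitylome, 3 vs 3 replicates, two MS
      injections each, ubiquitylation-site level.
    * ``panub`` — pan-ubiquitin enriched proteome, 4 vs 8 replicates,
      protein level.
    """
    return {
        "proteome": Design(
            name="proteome",
            condition_a="parental",
            condition_b="ko",
            n_reps_a=3,
            n_reps_b=6,
            n_fractions=6,
            n_tech_reps=1,
            feature_level="protein",
        ),
        "digly": Design(
            name="digly",
            condition_a="parental",
            condition_b="ko",
            n_reps_a=3,
            n_reps_b=3,
            n_fractions=1,
            n_tech_reps=2,
            feature_level="site",
        ),
        "panub": Design(
            name="panub",
            condition_a="parental",
            condition_b="ko",
            n_reps_a=4,
            n_reps_b=8,
            n_fractions=1,
            n_tech_reps=1,
            feature_level="protein",
        ),
    }


def _assign_flags(n: int, params: TruthParams, rng: np.random.Generator):
    n_changed = round(params.frac_changed * n)
    n_spec_a = round(params.frac_specific_a * n)
    n_spec_b = round(params.frac_specific_b * n)
    perm = rng.permutation(n)
    flags = np.array(["none"] * n, dtype=object)
    delta = np.zeros(n)
    delta[perm[:n_changed]] = params.log2fc_changed
    flags[perm[n_changed : n_changed + n_spec_a]] = "a_only"
    flags[perm[n_changed + n_spec_a : n_changed + n_spec_a + n_spec_b]] = "b_only"
    return delta, flags


def simulate_experiment(
    design: Design, params: TruthParams
) -> tuple[QuantTable, SimulationTruth]:
    """Simulate one experiment under ``design`` with known ground truth.

    Returns the raw-stage :class:`QuantTable` (fractionated and with
    technical replicates if the design says so) and the matching
    :class:`SimulationTruth`. Identical ``(design, params)`` produce
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_features
    site_level = design.feature_level == "site"

    # --- feature block -----------------------------------------------------
    protein_ids = np.array([f"P{i:05d}" for i in range(n)])
    gene_symbols = np.array([f"GENE{i}" for i in range(n)])
    positions = rng.integers(1, 800, size=n)  # lysine position, site designs
    delta, flags = _assign_flags(n, params, rng)
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)
    n_peps = rng.integers(
        params.peptides_per_feature[0], params.peptides_per_feature[1] + 1, size=n
    )

    feature_ids = np.where(
        site_level,
        np.char.add(np.char.add(protein_ids.astype(str), "_K"), positions.astype(str)),
        protein_ids,
    )

    # --- peptide block -----------------------------------------------------
    total_peps = int(n_peps.sum())
    pep_effect = rng.normal(0.0, params.sigma_peptide, total_peps)
    pep_feature_idx = np.repeat(np.arange(n), n_peps)
    pep_within = np.concatenate([np.arange(k) for k in n_peps])
    pep_keys = np.array(
        [
            f"{protein_ids[i]}_pep{j + 1}"
            for i, j in zip(pep_feature_idx, pep_within)
        ]
    )

    # --- replicate effects -------------------------------------------------
    conditions = list(design.conditions)
    rep_effect = {
        (c, r + 1): e
        for c in conditions
        for r, e in enumerate(
            rng.normal(0.0, params.sigma_rep, design.n_reps(c))
        )
    }

    # --- observation grid --------------------------------------------------
    cells = [
        (c, r)
        for c in conditions
        for r in range(1, design.n_reps(c) + 1)
    ]
    n_cells = len(cells)
    n_bio = total_peps * n_cells
    eps = rng.normal(0.0, params.sigma_noise, n_bio)
    tau = rng.normal(0.0, params.sigma_tech, n_bio * design.n_tech_reps)

    pep_idx = np.repeat(np.arange(total_peps), n_cells)
    cell_idx = np.tile(np.arange(n_cells), total_peps)
    feat_idx = pep_feature_idx[pep_idx]
    cond_arr = np.array([cells[i][0] for i in cell_idx], dtype=object)
    rep_arr = np.array([cells[i][1] for i in cell_idx])
    rep_eff_arr = np.array([rep_effect[(c, r)] for c, r in zip(cond_arr, rep_arr)])
    is_b = cond_arr == design.condition_b

    bio_log2 = (
        baseline[feat_idx]
        + pep_effect[pep_idx]
        + rep_eff_arr
        + delta[feat_idx] * is_b
        + eps
    )

    # expand technical replicates
    t = design.n_tech_reps
    obs_log2 = np.repeat(bio_log2, t) + tau
    obs_pep = np.repeat(pep_idx, t)
    obs_feat = np.repeat(feat_idx, t)
    obs_cond = np.repeat(cond_arr, t)
    obs_rep = np.repeat(rep_arr, t)
    obs_tech = np.tile(np.arange(1, t + 1), n_bio)

    # --- outliers ----------------------------------------------------------
    n_obs = obs_log2.size
    out_mask = rng.random(n_obs) < params.outlier_rate
    obs_log2 = obs_log2 + np.where(out_mask, params.outlier_shift, 0.0)

    # --- missingness -------------------------------------------------------
    u_miss = rng.random(n_obs)
    if params.missing_intensity_beta > 0 and 0 < params.missing_rate_base < 1:
        p_miss = expit(
            logit(params.missing_rate_base)
            - params.missing_intensity_beta
            * (obs_log2 - params.baseline_log2_mean)
        )
    else:
        p_miss = np.full(n_obs, params.missing_rate_base)
    drop = u_miss < p_miss

    # --- fraction split ----------------------------------------------------
    # A peptide elutes in few adjacent high-pH fractions; emulated as a
    # split over at most two randomly chosen fractions per observation.
    if design.n_fractions > 1:
        n_used = rng.integers(1, 3, size=n_obs)
        frac_first = rng.integers(0, design.n_fractions, size=n_obs)
        frac_offset = rng.integers(1, design.n_fractions, size=n_obs)
        frac_second = (frac_first + frac_offset) % design.n_fractions
        w = rng.uniform(0.05, 0.95, size=n_obs)
    else:
        n_used = np.ones(n_obs, dtype=int)
        frac_first = np.zeros(n_obs, dtype=int)
        frac_second = np.zeros(n_obs, dtype=int)
        w = np.ones(n_obs)

    # condition-specific features: drop the other condition entirely
    spec_drop = np.zeros(n_obs, dtype=bool)
    obs_flags = flags[obs_feat]
    spec_drop |= (obs_flags == "a_only") & (obs_cond == design.condition_b)
    spec_drop |= (obs_flags == "b_only") & (obs_cond == design.condition_a)
    keep = ~(drop | spec_drop)

    outlier_keys = [
        (pep_keys[p], c, int(r), int(tr))
        for p, c, r, tr in zip(
            obs_pep[out_mask & keep],
            obs_cond[out_mask & keep],
            obs_rep[out_mask & keep],
            obs_tech[out_mask & keep],
        )
    ]

    # --- assemble rows -----------------------------------------------------
    linear = np.power(2.0, obs_log2)
    rows_pep, rows_cond, rows_rep, rows_tech, rows_frac, rows_xic, rows_feat = (
        [],
        [],
        [],
        [],
        [],
        [],
        [],
    )
    idx = np.nonzero(keep)[0]
    for i in idx:
        splits = (
            [(frac_first[i], w[i]), (frac_second[i], 1.0 - w[i])]
            if (design.n_fractions > 1 and n_used[i] == 2)
            else [(frac_first[i], 1.0)]
        )
        for frac, weight in splits:
            rows_pep.append(obs_pep[i])
            rows_cond.append(obs_cond[i])
            rows_rep.append(obs_rep[i])
            rows_tech.append(obs_tech[i])
            rows_frac.append(frac + 1)
            rows_xic.append(linear[i] * weight)
            rows_feat.append(obs_feat[i])

    rows_pep = np.asarray(rows_pep, dtype=int)
    rows_feat = np.asarray(rows_feat, dtype=int)
    gg_col = [
        (int(positions[f]),) if site_level else () for f in rows_feat
    ]
    df = pd.DataFrame(
        {
            "protein_id": protein_ids[rows_feat],
            "gene_symbol": gene_symbols[rows_feat],
            "peptide_key": pep_keys[rows_pep],
            "is_proteotypic": True,
            "gg_positions": gg_col,
            "condition": rows_cond,
            "bio_rep": np.asarray(rows_rep, dtype=np.int64),
            "tech_rep": np.asarray(rows_tech, dtype=np.int64),
            "fraction": np.asarray(rows_frac, dtype=np.int64),
            "xic": np.asarray(rows_xic, dtype=float),
        }
    )

    truth_df = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "protein_id": protein_ids,
            "true_log2fc": np.where(flags == "none", delta, np.nan),
            "specific_flag": flags,
        }
    )
    table = QuantTable(design=design, data=df, stage=Stage.RAW).validate()
    truth = SimulationTruth(
        features=truth_df, outlier_observations=outlier_keys, seed=params.seed
    )
    return table, truth


# ---------------------------------------------------------------------------
# deterministic toy fixture
# ---------------------------------------------------------------------------

_PEP_OFFSETS = [0.0, 0.8, -0.6, 0.4]
_FIXTURE_SEED = 20210521
_FIXTURE_NOISE_SD = 0.25
_FIXTURE_REP_SD = 0.1


def fixture_toy_table() -> tuple[QuantTable, SimulationTruth]:
    """A small hand-constructed experiment used as a deterministic oracle.

    Six focal features under the 4-vs-8 pan-UB design: a 4-fold increase
    (``UPQ1``), a 4-fold decrease (``DWN1``), one feature observed only in
    the reference condition (``SPA1``), one only in the perturbed
    condition (``SPB1``), a three-peptide null (``NUL1``) and a
    single-peptide null (``NUL2``). Ten two-peptide background nulls
    (``BG01``..``BG10``) are included so that the per-replicate median and
    MAD used by normalization are estimated from a realistic spread of
    intensities. Feature composition and effects are fixed constants;
    observation noise comes from a frozen internal seed, so the table is
    bit-identical on every call.
    """
    design = make_builtin_designs()["panub"]
    rng = np.random.default_rng(_FIXTURE_SEED)
    features = [
        # (feature_id, base_log2, delta, flag, n_peptides)
        ("UPQ1", 20.0, 2.0, "none", 3),
        ("DWN1", 21.0, -2.0, "none", 3),
        ("SPA1", 19.5, np.nan, "a_only", 2),
        ("SPB1", 20.5, np.nan, "b_only", 2),
        ("NUL1", 20.0, 0.0, "none", 3),
        ("NUL2", 21.5, 0.0, "none", 1),
    ] + [
        (f"BG{i:02d}", 18.0 + 0.45 * i, 0.0, "none", 2) for i in range(1, 11)
    ]
    rep_shift = {
        (c, r): rng.normal(0.0, _FIXTURE_REP_SD)
        for c in design.conditions
        for r in range(1, design.n_reps(c) + 1)
    }
    rows = []
    for fid, base, delta, flag, k in features:
        for j in range(k):
            pep = f"{fid}_pep{j + 1}"
            for cond in design.conditions:
                if flag == "a_only" and cond == design.condition_b:
                    continue
                if flag == "b_only" and cond == design.condition_a:
                    continue
                shift = (
                    delta
                    if (cond == design.condition_b and flag == "none")
                    else 0.0
                )
                for r in range(1, design.n_reps(cond) + 1):
                    log2_val = (
                        base
                        + _PEP_OFFSETS[j]
                        + shift
                        + rep_shift[(cond, r)]
                        + rng.normal(0.0, _FIXTURE_NOISE_SD)
                    )
                    rows.append(
                        {
                            "protein_id": fid,
                            "gene_symbol": fid,
                            "peptide_key": pep,
                            "is_proteotypic": True,
                            "gg_positions": (),
                            "condition": cond,
                            "bio_rep": r,
                            "tech_rep": 1,
                            "fraction": 1,
                            "xic": float(2.0 ** log2_val),
                        }
                    )
    df = pd.DataFrame(rows)
    for col in ("bio_rep", "tech_rep", "fraction"):
        df[col] = df[col].astype(np.int64)
    table = QuantTable(design=design, data=df, stage=Stage.RAW).validate()
    truth = SimulationTruth(
        features=pd.DataFrame(
            {
                "feature_id": [f[0] for f in features],
                "protein_id": [f[0] for f in features],
                "true_log2fc": [f[2] for f in features],
                "specific_flag": [f[3] for f in features],
            }
        ),
        outlier_observations=[],
        seed=0,
    )
    return table, truth
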