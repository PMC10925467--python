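"""Seeded synthetic cohorts, lipidomes, protein-module matrices, and MS/MS spectra.

The generator emulates the statistical structure of a three-group
(Control / AAD / SAD) autopsy brain cohort with an untargeted lipidomics run:

* neuropathology (CERAD, Braak) and cognition sampled inside the region of
  each diagnosis rule, so the planted group label is exactly recoverable;
* clinical traits (global cognition, pathology burden, age) with
  group-ordered means; PMI and education group-independent;
* lipid features in shorthand-named classes, block-correlated through planted
  module latent factors, with a lysophospholipid module shifted down in the
  SAD group (default -0.8 sd on the log2 scale);
* monotone multiplicative injection-order drift (a minority of features drift
  strongly), QC-pool injections interspersed through the run;
* protein-module eigenvalue columns sharing latent factors with chosen lipid
  modules; negative-mode lyso-spectra with or without the sn-1 diagnostic.

Everything is driven by a single integer seed and emits a GroundTruth object
sufficient to score recovery at every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import MsmsSpectrum, parse_lipid_name, predict_lyso_fragments
from .classify import NeuropathRecord, classify_case, is_demented
from .preprocess import FeatureTable

GROUPS = ("Control", "AAD", "SAD")


@dataclass
class ModuleSpec:
    size: int
    intra_cor: float = 0.7
    classes: Optional[tuple] = None  # restrict member features to these classes
    trait: Optional[str] = None  # "diagnosis" or a continuous trait name
    effect_sd: float = 0.0  # shift (in log2-sd units) in SAD, or slope on the trait

    def __post_init__(self):
        if not 0 <= self.intra_cor < 1:
            raise ValueError("intra-correlation must lie in [0, 1)")


def default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec(20, 0.7, ("LPE", "LPC"), "diagnosis", -0.8),
        ModuleSpec(20, 0.7, ("TAG",), "braak", 0.25),
        ModuleSpec(20, 0.7, ("PC", "PE")),
        ModuleSpec(20, 0.7, ("Cer", "SM")),
        ModuleSpec(20, 0.7, ("PI", "PS", "PG")),
        ModuleSpec(20, 0.7, ("DAG", "MAG")),
    ]


#: Rough lipid-class composition of the simulated brain lipidome.
DEFAULT_CLASS_WEIGHTS = {
    "TAG": 0.18, "PC": 0.13, "PE": 0.10, "SM": 0.07, "Cer": 0.06,
    "PS": 0.06, "PI": 0.05, "PG": 0.04, "LPE": 0.08, "LPC": 0.07,
    "DAG": 0.05, "MAG": 0.03, "AcCa": 0.03, "ChE": 0.02, "PE_p": 0.03,
}


@dataclass
class CouplingSpec:
    lipid_module: int
    protein_module: str
    r: float


@dataclass
class SimConfig:
    seed: int
    n_control: int = 92
    n_aad: int = 77
    n_sad: int = 147
    n_features: int = 343
    n_qc: int = 40
    n_batches: int = 1
    modules: list = field(default_factory=default_modules)
    drift_span: float = 0.30  # linear fractional span of the run-order drift
    heavy_drift_frac: float = 0.10
    qc_noise_sd: float = 0.05  # log2-scale technical noise of QC pools
    feature_sd: float = 0.5  # log2-scale biological sd
    missing_rate: float = 0.02
    qc_fail_frac: float = 0.15  # fraction of features failing the QC filter
    n_internal_standards: int = 4
    couplings: list = field(default_factory=lambda: [CouplingSpec(1, "black", 0.8)])
    n_protein_modules: int = 12
    n_common: int = 266  # samples shared with the protein dataset
    class_weights: Optional[dict] = None  # lipid-class composition override

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_control, self.n_aad, self.n_sad) < 3:
            raise ValueError("group sizes must be >= 3")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_aad + self.n_sad


@dataclass
class GroundTruth:
    module_labels: pd.Series  # feature -> planted module id (0 = background)
    differential: pd.DataFrame  # feature, effect_sd, group
    latents: pd.DataFrame  # study samples x planted modules
    couplings: list  # list of CouplingSpec actually emitted
    sn_labels: dict = field(default_factory=dict)  # spectrum title -> sn1/sn2

    def to_json(self, path: str) -> None:
        obj = {
            "module_labels": self.module_labels.to_dict(),
            "differential": self.differential.to_dict(orient="records"),
            "couplings": [asdict(c) for c in self.couplings],
            "sn_labels": self.sn_labels,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def generate_cohort(config: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Sample a traits table whose planted diagnosis the classification rules reproduce."""
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    specs = [
        ("Control", config.n_control), ("AAD", config.n_aad), ("SAD", config.n_sad)
    ]
    cog_mu = {"Control": 0.25, "AAD": -0.09, "SAD": -1.29}
    age_mu = {"Control": 84.0, "AAD": 88.0, "SAD": 89.0}
    path_mu = {"Control": 0.3, "AAD": 0.8, "SAD": 1.2}
    i = 0
    for group, n in specs:
        for _ in range(n):
            if group == "Control":
                braak = int(rng.choice([0, 1, 2, 3], p=[0.2, 0.35, 0.35, 0.1]))
                cerad = 0 if braak == 3 else int(rng.choice([0, 1]))
                mmse = float(np.clip(rng.normal(28.3, 1.2), 24.0, 30.0))
                casi = float(np.clip(rng.normal(92, 4), 81.0, 100.0))
                cdr = float(rng.choice([0.0, 0.5], p=[0.8, 0.2]))
            elif group == "AAD":
                braak = int(rng.choice([3, 4, 5, 6], p=[0.4, 0.35, 0.2, 0.05]))
                cerad = int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))
                mmse = float(np.clip(rng.normal(27.5, 1.4), 24.0, 30.0))
                casi = float(np.clip(rng.normal(89, 4), 81.0, 100.0))
                cdr = float(rng.choice([0.0, 0.5], p=[0.7, 0.3]))
            else:
                braak = int(rng.choice([3, 4, 5, 6], p=[0.15, 0.3, 0.35, 0.2]))
                cerad = int(rng.choice([2, 3]))
                mmse = float(rng.uniform(5.0, 23.5))
                casi = float(rng.uniform(40.0, 80.5))
                cdr = float(rng.choice([1.0, 2.0, 3.0], p=[0.5, 0.3, 0.2]))
            rec = NeuropathRecord(cerad=cerad, braak=braak, mmse=mmse, casi=casi, cdr=cdr)
            call = classify_case(rec)
            if call.call.value != group:
                raise RuntimeError(
                    f"generator produced a record the rules classify as {call.call.value}, "
                    f"expected {group}"
                )
            gpath = max(rng.normal(path_mu[group], 0.3), 0.0)
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "diagnosis": group,
                    "cerad": cerad,
                    "braak": braak,
                    "mmse": round(mmse, 1),
                    "casi": round(casi, 1),
                    "cdr": cdr,
                    "dementia": is_demented(rec),
                    "cognition": rng.normal(cog_mu[group], 0.55),
                    "gpath": gpath,
                    "amyloid": max(rng.normal(path_mu[group] * 1.5, 0.6), 0.0),
                    "tangles": max(rng.normal(path_mu[group] * 2.0, 0.9), 0.0),
                    "reagan_inverted": int(
                        np.clip(round(rng.normal({"Control": 3.4, "AAD": 2.2, "SAD": 1.7}[group], 0.6)), 1, 4)
                    ),
                    "age": float(np.clip(rng.normal(age_mu[group], 5.5), 66, 102)),
                    "sex_female": int(rng.random() < 0.67),
                    "education": float(np.clip(rng.normal(16.2, 3.0), 8, 28)),
                    "pmi": float(np.clip(rng.normal(7.2, 3.0), 1.0, 24.0)),
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


# --- lipid name pools ------------------------------------------------------

_CHAIN_CARBONS = [14, 15, 16, 17, 18, 20, 22, 24]
_N_CHAINS = {"LPE": 1, "LPC": 1, "MAG": 1, "AcCa": 1, "ChE": 1, "PE_p": 2}


def _candidate_names(cls: str, rng: np.random.Generator, n_needed: int) -> list[str]:
    n_chains = _N_CHAINS.get(cls, {"TAG": 3}.get(cls, 2))
    names: set[str] = set()
    attempts = 0
    while len(names) < n_needed and attempts < 50 * n_needed + 200:
        attempts += 1
        chains = []
        for _ in range(n_chains):
            c = int(rng.choice(_CHAIN_CARBONS))
            d = int(rng.integers(0, min(7, max(1, c // 3))))
            chains.append(f"{c}:{d}")
        names.add(f"{cls} " + "_".join(sorted(chains)))
    return sorted(names)[:n_needed]


def generate_lipidome(
    cohort: pd.DataFrame, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate the samples x lipids table with module structure, drift, QC pools."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n_study = len(cohort)
    total_module = sum(m.size for m in config.modules)
    if total_module > config.n_features:
        raise ValueError("planted module sizes exceed the feature count")

    # allocate feature names by class, honouring module class restrictions
    weights = config.class_weights or DEFAULT_CLASS_WEIGHTS
    counts = {
        cls: max(1, int(round(w * config.n_features)))
        for cls, w in weights.items()
    }
    while sum(counts.values()) > config.n_features:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < config.n_features:
        counts[min(counts, key=counts.get)] += 1
    pool = {cls: _candidate_names(cls, rng, n) for cls, n in counts.items()}
    for cls in pool:  # top up if the combinatorial pool ran short
        while len(pool[cls]) < counts[cls]:
            extra = _candidate_names(cls, rng, counts[cls] + 10)
            pool[cls] = sorted(set(pool[cls]) | set(extra))[: counts[cls]]

    module_labels = {}
    used: set[str] = set()
    for mid, spec in enumerate(config.modules, start=1):
        classes = spec.classes or tuple(pool)
        candidates = [n for c in classes for n in pool.get(c, []) if n not in used]
        if len(candidates) < spec.size:
            raise ValueError(f"not enough features of classes {classes} for module {mid}")
        chosen = list(rng.choice(candidates, size=spec.size, replace=False))
        for name in chosen:
            module_labels[name] = mid
            used.add(name)
    features = [n for cls in sorted(pool) for n in pool[cls]]
    rng.shuffle(features)
    labels = pd.Series([module_labels.get(f, 0) for f in features], index=features)

    # latent module factors over study samples, with planted trait coupling
    latents = pd.DataFrame(
        rng.standard_normal((n_study, len(config.modules))),
        index=cohort.index,
        columns=[f"L{m}" for m in range(1, len(config.modules) + 1)],
    )
    diff_rows = []
    sad_mask = (cohort["diagnosis"] == "SAD").to_numpy()

    mu = rng.uniform(10, 20, size=len(features))
    sigma = config.feature_sd
    log2_study = np.empty((n_study, len(features)))
    for j, feat in enumerate(features):
        mid = labels.iloc[j]
        if mid == 0:
            signal = rng.standard_normal(n_study)
        else:
            spec = config.modules[mid - 1]
            rho = spec.intra_cor
            f = latents.iloc[:, mid - 1].to_numpy()
            signal = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n_study)
            if spec.trait == "diagnosis" and spec.effect_sd:
                signal = signal + spec.effect_sd * sad_mask
                diff_rows.append({"feature": feat, "effect_sd": spec.effect_sd, "group": "SAD"})
            elif spec.trait and spec.effect_sd:
                tr = cohort[spec.trait].to_numpy(dtype=float)
                trz = (tr - tr.mean()) / (tr.std() or 1.0)
                signal = signal + spec.effect_sd * trz
        log2_study[:, j] = mu[j] + sigma * signal

    # assemble the injection sequence: QC pool every `step` injections
    n_total = n_study + config.n_qc
    step = max(n_total // max(config.n_qc, 1), 2)
    qc_positions = set(range(1, n_total + 1, step))
    while len(qc_positions) > config.n_qc:
        qc_positions.pop()
    sample_ids, is_qc, inj_order = [], [], []
    study_rows = {sid: log2_study[i] for i, sid in enumerate(cohort.index)}
    log2_all = []
    qc_profile = mu  # pooled aliquot of everything: the mean profile
    qi = 0
    # randomized run order, as in practice, so drift is not confounded with group
    study_iter = iter(rng.permutation(np.array(cohort.index)))
    for pos in range(1, n_total + 1):
        if pos in qc_positions:
            qi += 1
            sample_ids.append(f"QC{qi:03d}")
            is_qc.append(True)
            log2_all.append(qc_profile + rng.normal(0, config.qc_noise_sd, len(features)))
        else:
            sid = next(study_iter)
            sample_ids.append(sid)
            is_qc.append(False)
            log2_all.append(study_rows[sid])
        inj_order.append(pos)
    log2_all = np.array(log2_all)

    # monotone multiplicative drift; a minority of features drift strongly
    span = config.drift_span
    base_slope = np.log2((1 + span / 2) / (1 - span / 2)) if span > 0 else 0.0
    mult = rng.uniform(0.5, 1.5, len(features))
    heavy = rng.random(len(features)) < config.heavy_drift_frac
    mult[heavy] = rng.uniform(4.0, 7.0, heavy.sum())
    sign = np.where(rng.random(len(features)) < 0.5, 1.0, -1.0)
    slopes = base_slope * mult * sign
    x = (np.array(inj_order) - 1) / max(n_total - 1, 1)
    log2_all = log2_all + np.outer(x - 0.5, slopes)

    abundance = 2.0 ** log2_all
    if config.missing_rate > 0:
        mask = rng.random(abundance.shape) < config.missing_rate
        mask[np.array(is_qc)] = False  # QC pools are always measured
        abundance[mask] = np.nan

    # per-feature QC metrics; internal standards appended
    n_feat = len(features)
    fail = rng.random(n_feat) < config.qc_fail_frac
    snr = np.where(fail, rng.uniform(0.5, 3.0, n_feat), 3.0 + rng.exponential(10.0, n_feat) + 0.5)
    quality = np.where(fail, rng.uniform(0.1, 0.6, n_feat), rng.uniform(0.62, 0.99, n_feat))
    grade = rng.choice(["A", "B", "C"], size=n_feat, p=[0.5, 0.3, 0.2]).astype(object)
    fail_mode = rng.integers(0, 3, n_feat)
    for j in np.flatnonzero(fail):
        if fail_mode[j] == 0:
            snr[j] = rng.uniform(0.5, 3.0)
            quality[j] = rng.uniform(0.65, 0.95)
        elif fail_mode[j] == 1:
            snr[j] = 3.5 + rng.exponential(10.0)
            quality[j] = rng.uniform(0.1, 0.6)
        else:
            snr[j] = 3.5 + rng.exponential(10.0)
            quality[j] = rng.uniform(0.65, 0.95)
            grade[j] = "D"

    is_names = [f"LPE 18:1D{k+4}" for k in range(config.n_internal_standards)]
    is_ab = 2.0 ** (
        14.0 + rng.normal(0, config.qc_noise_sd, (n_total, len(is_names)))
    )
    all_features = features + is_names
    abundance = np.column_stack([abundance, is_ab])
    feature_meta = pd.DataFrame(
        {
            "species": all_features,
            "snr": np.concatenate([snr, np.full(len(is_names), 50.0)]),
            "peak_quality": np.concatenate([quality, np.full(len(is_names), 0.95)]),
            "id_grade": list(grade) + ["A"] * len(is_names),
            "is_internal_standard": [False] * n_feat + [True] * len(is_names),
        },
        index=all_features,
    )
    sample_meta = pd.DataFrame(
        {
            "is_qc_pool": is_qc,
            "batch": [f"B{1 + (o - 1) * config.n_batches // n_total}" for o in inj_order],
            "injection_order": inj_order,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = FeatureTable(
        pd.DataFrame(abundance, index=sample_meta.index, columns=all_features),
        feature_meta,
        sample_meta,
    )
    gt = GroundTruth(
        module_labels=labels,
        differential=pd.DataFrame(diff_rows, columns=["feature", "effect_sd", "group"]),
        latents=latents,
        couplings=list(config.couplings),
    )
    return table, gt


PROTEIN_MODULE_NAMES = [
    "black", "green", "greenyellow", "lightgreen", "lightcyan", "darkgreen",
    "blue", "brown", "yellow", "turquoise", "red", "pink", "magenta", "purple",
    "salmon", "cyan", "tan", "grey60",
]


def generate_protein_modules(
    cohort: pd.DataFrame,
    gt: GroundTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Protein-module eigenvalue matrix on the common-sample subset.

    Modules named in ``config.couplings`` share the referenced lipid-module
    latent at the requested correlation; the remainder are independent noise.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    common = cohort.index[: min(config.n_common, len(cohort))]
    names = PROTEIN_MODULE_NAMES[: config.n_protein_modules]
    cols = {}
    coupled = {c.protein_module: c for c in config.couplings}
    for nm in names:
        noise = rng.standard_normal(len(common))
        if nm in coupled:
            c = coupled[nm]
            if f"L{c.lipid_module}" not in gt.latents.columns:
                raise ValueError(f"unknown lipid module {c.lipid_module} in coupling spec")
            f = gt.latents.loc[common, f"L{c.lipid_module}"].to_numpy()
            cols[nm] = c.r * f + np.sqrt(1 - c.r**2) * noise
        else:
            cols[nm] = noise
    return pd.DataFrame(cols, index=common)


def generate_spectra(
    species_sn: Sequence[tuple[str, str]],
    ppm_jitter: float = 10.0,
    n_decoys: int = 20,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[list[MsmsSpectrum], dict]:
    """Negative-mode lyso-spectra for (species name, sn label) pairs.

    Theoretical fragments are jittered uniformly within ``ppm_jitter``;
    sn-2 spectra omit the headgroup-retention diagnostic; decoy peaks avoid
    a 3x tolerance window around every theoretical fragment; sn-2 isomers
    are assigned earlier retention times than sn-1.
    """
    rng = rng or np.random.default_rng(seed)
    spectra = []
    truth = {}
    for k, (name, sn) in enumerate(species_sn):
        sp = parse_lipid_name(name)
        frags = predict_lyso_fragments(sp)
        peaks = []
        for fr in frags:
            if sn == "sn2" and fr.diagnostic_sn1:
                continue
            mz = fr.mz * (1 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6)
            peaks.append((mz, float(rng.lognormal(10, 1))))
        precursor = frags[0].mz
        lo, hi = 100.0, precursor + 60.0
        forbidden = [fr.mz for fr in frags]
        added = 0
        while added < n_decoys:
            mz = rng.uniform(lo, hi)
            if all(abs(mz - f) > 3 * ppm_jitter * 1e-6 * f + 0.01 for f in forbidden):
                peaks.append((mz, float(rng.lognormal(7, 1))))
                added += 1
        base_rt = float(rng.uniform(4.0, 9.0))
        rt = base_rt + (0.4 if sn == "sn1" else 0.0)
        title = f"spec{k:04d}|{name}|{sn}"
        spectra.append(
            MsmsSpectrum(
                precursor_mz=precursor,
                polarity="-",
                peaks=peaks,
                retention_time=rt,
                title=title,
            )
        )
        truth[title] = sn
    return spectra, truth


@dataclass
class SimResult:
    cohort: pd.DataFrame
    lipidome: FeatureTable
    ground_truth: GroundTruth
    protein_modules: pd.DataFrame


def simulate_all(config: SimConfig) -> SimResult:
    """Run the full generator chain under one seed."""
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config, rng)
    lipidome, gt = generate_lipidome(cohort, config, rng)
    proteins = generate_protein_modules(cohort, gt, config, rng)
    return SimResult(cohort, lipidome, gt, proteins)
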