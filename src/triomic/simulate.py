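"""Seeded generator of paired tumour / normal-mucosa / stool genus count
tables with planted structure, plus the matching clinical covariates and a
ground-truth record.

The model is logistic-normal multinomial: per sample, genus log-abundances
are a baseline plus planted environment, subtype, patient and noise terms;
proportions are the softmax of the log-abundances and counts are a
multinomial draw at a log-normally distributed sequencing depth.  Planted
effects therefore live directly in clr space, where the downstream
analysis operates.

Environment effects are planted symmetrically (half the configured effect
up in the preferred environments, half down elsewhere) and balanced so the
mean planted log-shift is equal in every environment: stool-preference
genera absorb the counter-shift that offsets the mucosal enrichment of the
tumour-side genera.  Two failure modes are avoided this way.  Without the
mean balance, the clr closure term smears an artefactual ~0.4-clr shift
over every unplanted genus (a composition cannot gain mass somewhere
without apparently losing it elsewhere).  Without the symmetric split, one
environment becomes much more concentrated than the others, rare genera
drop below the detection limit there specifically, and the zero
replacement turns that censoring into spurious paired differences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ClinicalTable, GenusCountTable

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "write_fixture"]


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic triplet generator."""

    n_patients: int = 120
    n_genera: int = 200
    # planted genera per category; the remainder are no-difference.
    # "tumour" plants a half-effect shift on normal mucosa and is off by
    # default: with paired n in the hundreds any intermediate normal level
    # is itself significant, which reassigns the genus to mucosa or
    # tumour_specific — the plain-tumour class has no cleanly plantable
    # effect pattern.
    n_mucosa: int = 40
    n_tumour_specific: int = 40
    n_stool: int = 40
    n_tumour: int = 0
    effect: float = 2.0                # clr shift of planted environment effects
    n_subtypes: int = 3
    subtype_weights: tuple = (0.26, 0.31, 0.43)
    subtype_effect: float = 2.0        # extra tumour-mucosa clr shift on signature genera
    signature_size: int = 10           # signature genera per subtype (from tumour_specific pool)
    patient_sd: float = 0.5            # patient random effect, shared across the triplet
    noise_sd: float = 1.0              # per-sample, per-genus log-abundance noise
    baseline_sd: float = 1.25          # spread of genus baseline log-abundances
    depth_meanlog: float = float(np.log(20_000.0))
    depth_sdlog: float = 0.6
    depth_bounds: tuple = (3_000, 240_000)
    # optional planted clinical effects (tumour samples only)
    n_grade_slope_genera: int = 0
    grade_slope: float = 1.0           # clr shift per grade step
    n_interaction_genera: int = 0
    interaction_cell: tuple = ("3", "right_transverse")
    interaction_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_mucosa + self.n_tumour_specific + self.n_stool + self.n_tumour
        if planted > self.n_genera:
            raise ValueError("category plan exceeds n_genera")
        if abs(sum(self.subtype_weights) - 1.0) > 1e-9:
            raise ValueError("subtype weights must sum to 1")
        if len(self.subtype_weights) != self.n_subtypes:
            raise ValueError("one weight per subtype required")
        if min(self.patient_sd, self.noise_sd, self.baseline_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_subtypes * self.signature_size > self.n_tumour_specific and self.subtype_effect:
            raise ValueError("not enough tumour_specific genera for the subtype signatures")

    @classmethod
    def scaled(cls, n_patients: int, n_genera: int, seed: int = 0, **overrides) -> "GeneratorConfig":
        """A config with the default category proportions (one fifth of the
        genera per planted category) scaled to a smaller table."""
        per = n_genera // 5
        sig = max(1, per // 3)
        return cls(
            n_patients=n_patients,
            n_genera=n_genera,
            n_mucosa=per,
            n_tumour_specific=per,
            n_stool=per,
            signature_size=min(sig, per // 3) if per >= 3 else 0,
            seed=seed,
            **overrides,
        )

    @property
    def n_no_difference(self) -> int:
        return self.n_genera - (
            self.n_mucosa + self.n_tumour_specific + self.n_stool + self.n_tumour
        )


@dataclass
class GroundTruth:
    """Planted labels: per-genus category/origin/signature, per-patient subtype."""

    genus: pd.DataFrame      # index genus_id: category, origin, signature_subtype
    patients: pd.DataFrame   # index patient_id: subtype
    config: GeneratorConfig = field(repr=False, default=None)


# subtype-conditional grade/location tables, calibrated to the published
# subtype-conditional frequencies (subtype 1: right-sided, high grade);
# the remaining covariates are drawn from cohort marginals, independent of
# subtype
_GRADE_LEVELS = ["NA_in_situ", "1", "2", "3"]
_GRADE_PROBS = {
    0: (0.000, 0.022, 0.391, 0.587),
    1: (0.055, 0.091, 0.672, 0.182),
    2: (0.052, 0.156, 0.610, 0.182),
}
_LOC_LEVELS = ["right", "transverse", "left", "rectosigmoideum", "rectum"]
_LOC_PROBS = {
    0: (0.609, 0.130, 0.087, 0.130, 0.044),
    1: (0.200, 0.091, 0.309, 0.182, 0.218),
    2: (0.325, 0.104, 0.299, 0.208, 0.064),
}
_AJCC_LEVELS = ["0", "I", "II", "III", "IV"]
_AJCC_PROBS = (0.045, 0.174, 0.371, 0.270, 0.140)
_PT_LEVELS = ["pTis", "pT1", "pT2", "pT3", "pT4"]
_PT_PROBS = (0.045, 0.062, 0.180, 0.646, 0.067)
_PN_LEVELS = ["pN0", "pN1", "pN2"]
_PN_PROBS = (0.612, 0.258, 0.130)
_M_LEVELS = ["M0", "M1"]
_M_PROBS = (0.86, 0.14)
_MSI_LEVELS = ["MSI", "MSS", "NA"]
_MSI_PROBS = (0.152, 0.618, 0.230)
_MUT_LEVELS = ["wt", "mut", "NA"]
_BRAF_PROBS = (0.433, 0.067, 0.50)
_KRAS_PROBS = (0.135, 0.073, 0.792)
_NRAS_PROBS = (0.208, 0.011, 0.781)

_ENVS = ("tumour", "normal", "stool")


def _environment_shifts(cfg: GeneratorConfig, categories: np.ndarray) -> np.ndarray:
    """Per-genus log-abundance shifts for (tumour, normal, stool), balanced
    so the mean planted shift is equal in every environment.

    Mucosa-side genera are elevated on mucosa relative to stool; stool
    genera are elevated in stool (and mildly on normal mucosa) by the
    amounts that equalise the environment totals.  No genus is pushed
    below its baseline anywhere: depleting genera instead would drive them
    into the zero-replacement regime on mucosa, whose censoring biases the
    per-sample clr centring and smears artefactual paired shifts over the
    no-difference class.
    """
    shifts = np.zeros((cfg.n_genera, 3))  # columns: tumour, normal, stool
    mucosa = categories == "mucosa"
    ts = categories == "tumour_specific"
    plain = categories == "tumour"
    stool = categories == "stool"
    h = cfg.effect / 2.0  # half-effect, planted symmetrically around baseline
    shifts[mucosa] = (h, h, -h)
    shifts[ts] = (h, -h, -h)
    shifts[plain] = (h, 0.0, -h)
    n_stool = int(stool.sum())
    totals = shifts.sum(axis=0)
    if n_stool > 0:
        target = totals.mean()
        shifts[stool] = (target - totals) / n_stool
    elif np.ptp(totals) > 0:
        import warnings

        warnings.warn("no stool-category genera: environment shifts are unbalanced")
    return shifts


def generate(config: GeneratorConfig) -> tuple[GenusCountTable, ClinicalTable, GroundTruth]:
    """Draw one synthetic cohort: counts, clinical covariates, ground truth.

    Fully reproducible under ``config.seed``; independent random streams
    per component (layout, effects, depths, counts, clinical)."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_layout = np.random.default_rng(streams[0])
    rng_sample = np.random.default_rng(streams[1])
    rng_depth = np.random.default_rng(streams[2])
    rng_counts = np.random.default_rng(streams[3])
    rng_clin = np.random.default_rng(streams[4])

    g = cfg.n_genera
    genus_ids = [f"g{i:04d}" for i in range(g)]
    categories = np.array(
        ["mucosa"] * cfg.n_mucosa
        + ["tumour_specific"] * cfg.n_tumour_specific
        + ["stool"] * cfg.n_stool
        + ["tumour"] * cfg.n_tumour
        + ["no_difference"] * cfg.n_no_difference
    )
    baseline = rng_layout.normal(0.0, cfg.baseline_sd, g)
    env_shift = _environment_shifts(cfg, categories)

    # subtype signatures from the tumour_specific pool; the oral/gut origin
    # annotation is laid out so subtype 1 signatures are all oral, subtype 2
    # mixed, subtype 3 non-oral — planting an ordered oral fraction
    ts_idx = np.flatnonzero(categories == "tumour_specific")
    signature_subtype = np.full(g, -1)
    sig_sets = []
    for s in range(cfg.n_subtypes):
        block = ts_idx[s * cfg.signature_size : (s + 1) * cfg.signature_size]
        signature_subtype[block] = s
        sig_sets.append(block)
    origin = np.full(g, "gut", dtype=object)
    mucosa_idx = np.flatnonzero(categories == "mucosa")
    oral_mucosa = rng_layout.choice(mucosa_idx, size=len(mucosa_idx) // 2, replace=False)
    origin[oral_mucosa] = "oral"
    if len(sig_sets) >= 1:
        origin[sig_sets[0]] = "oral"
    if len(sig_sets) >= 2:
        half = cfg.signature_size // 2
        origin[sig_sets[1][:half]] = "oral"
        origin[sig_sets[1][half:]] = "gut"
    for s in range(2, cfg.n_subtypes):
        origin[sig_sets[s]] = "gut"
    # remaining (non-signature) tumour_specific genera: mostly oral
    rest_ts = ts_idx[signature_subtype[ts_idx] == -1]
    origin[rest_ts] = "oral"

    grade_idx = np.array([], dtype=int)
    inter_idx = np.array([], dtype=int)
    nd_idx = np.flatnonzero(categories == "no_difference")
    if cfg.n_grade_slope_genera:
        grade_idx = nd_idx[: cfg.n_grade_slope_genera]
    if cfg.n_interaction_genera:
        inter_idx = nd_idx[cfg.n_grade_slope_genera :][: cfg.n_interaction_genera]

    n = cfg.n_patients
    patient_ids = [f"P{i:03d}" for i in range(n)]
    subtype = rng_clin.choice(cfg.n_subtypes, size=n, p=cfg.subtype_weights)

    # clinical covariates (grade and location coupled to subtype)
    def draw(levels, probs, size):
        return rng_clin.choice(levels, size=size, p=probs)

    grade = np.array([draw(_GRADE_LEVELS, _GRADE_PROBS[min(z, 2)], 1)[0] for z in subtype])
    loc = np.array([draw(_LOC_LEVELS, _LOC_PROBS[min(z, 2)], 1)[0] for z in subtype])
    clinical = pd.DataFrame(
        {
            "age": np.round(rng_clin.normal(67.0, 10.7, n)).astype(int),
            "gender": draw(["male", "female"], (0.556, 0.444), n),
            "localisation": loc,
            "grade": grade,
            "ajcc": draw(_AJCC_LEVELS, _AJCC_PROBS, n),
            "pT": draw(_PT_LEVELS, _PT_PROBS, n),
            "pN": draw(_PN_LEVELS, _PN_PROBS, n),
            "M": draw(_M_LEVELS, _M_PROBS, n),
            "msi": draw(_MSI_LEVELS, _MSI_PROBS, n),
            "braf": draw(_MUT_LEVELS, _BRAF_PROBS, n),
            "kras": draw(_MUT_LEVELS, _KRAS_PROBS, n),
            "nras": draw(_MUT_LEVELS, _NRAS_PROBS, n),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )

    grade_num = pd.to_numeric(pd.Series(grade), errors="coerce").to_numpy()
    right_transverse = np.isin(loc, ("right", "transverse"))

    patient_effect = rng_sample.normal(0.0, cfg.patient_sd, (n, g))

    counts = np.zeros((g, 3 * n), dtype=np.int64)
    sample_ids = []
    meta_rows = []
    lo, hi = cfg.depth_bounds
    col = 0
    env_cols = {"tumour": 0, "normal": 1, "stool": 2}
    for i, pid in enumerate(patient_ids):
        for env in _ENVS:
            mean = baseline + patient_effect[i] + env_shift[:, env_cols[env]]
            if env == "tumour":
                # subtypes differ by presence AND absence: each subtype
                # lifts its own signature genera and depletes the next
                # subtype's, so the shift is zero-sum per sample and adds
                # no clr closure offset
                mean = mean + np.where(signature_subtype == subtype[i], cfg.subtype_effect, 0.0)
                if cfg.n_subtypes > 1:
                    anti = (subtype[i] + 1) % cfg.n_subtypes
                    mean = mean - np.where(signature_subtype == anti, cfg.subtype_effect, 0.0)
                if grade_idx.size and not np.isnan(grade_num[i]):
                    mean[grade_idx] += cfg.grade_slope * (grade_num[i] - 2.0)
                if inter_idx.size:
                    gr_t, loc_t = cfg.interaction_cell
                    in_cell = (
                        (str(int(grade_num[i])) == gr_t if not np.isnan(grade_num[i]) else False)
                        and ((loc_t == "right_transverse") == bool(right_transverse[i]))
                    )
                    if in_cell:
                        mean[inter_idx] += cfg.interaction_effect
            mean = mean + rng_sample.normal(0.0, cfg.noise_sd, g)
            p = np.exp(mean - mean.max())
            p /= p.sum()
            depth = int(np.clip(rng_depth.lognormal(cfg.depth_meanlog, cfg.depth_sdlog), lo, hi))
            counts[:, col] = rng_counts.multinomial(depth, p)
            sid = f"{pid}_{'T' if env == 'tumour' else 'VN' if env == 'normal' else 'S'}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "patient_id": pid, "sample_type": env})
            col += 1

    count_df = pd.DataFrame(counts, index=genus_ids, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = GenusCountTable(count_df, meta)

    genus_truth = pd.DataFrame(
        {
            "category": categories,
            "origin": origin,
            "signature_subtype": signature_subtype,
            "grade_slope_planted": np.isin(np.arange(g), grade_idx),
            "interaction_planted": np.isin(np.arange(g), inter_idx),
        },
        index=pd.Index(genus_ids, name="genus_id"),
    )
    patient_truth = pd.DataFrame(
        {"subtype": subtype}, index=pd.Index(patient_ids, name="patient_id")
    )
    truth = GroundTruth(genus=genus_truth, patients=patient_truth, config=cfg)
    return table, ClinicalTable(clinical), truth


def write_fixture(
    table: GenusCountTable,
    clinical: ClinicalTable,
    truth: GroundTruth,
    outdir,
) -> dict:
    """Write the generated tables as the TSVs the readers consume, plus the
    ground-truth tables and the generator config (YAML)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "sample_meta": out / "sample_meta.tsv",
        "clinical": out / "clinical.tsv",
        "annotation": out / "annotation.tsv",
        "truth_genus": out / "truth_genus.tsv",
        "truth_patients": out / "truth_patients.tsv",
        "config": out / "generator_config.yaml",
    }
    table.write(paths["counts"], paths["sample_meta"])
    clinical.data.rename_axis("patient_id").to_csv(paths["clinical"], sep="\t")
    truth.genus[["origin"]].rename_axis("genus_id").to_csv(paths["annotation"], sep="\t")
    truth.genus.rename_axis("genus_id").to_csv(paths["truth_genus"], sep="\t")
    truth.patients.rename_axis("patient_id").to_csv(paths["truth_patients"], sep="\t")
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(truth.config).items()
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
    return {k: str(v) for k, v in paths.items()}
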