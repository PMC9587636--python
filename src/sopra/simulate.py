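"""Synthetic cell-cycle screens with known ground truth.

The generator emulates the statistical structure of a DNA-stain (Hoechst)
cell-cycle assay read out per nucleus:

- Every cell carries a DNA content ``C`` drawn from a two-component mixture:
  a 2N (G1) mode and a 4N (G2/M) mode at exactly twice its center, log-normal
  within mode. Cycling control populations put weight ``w_2N`` (default 0.65)
  on the 2N mode.
- ``Total Intensity DAPI`` is proportional to ``C``; ``Area`` scales as
  ``C**a`` (sub-linear, default a = 0.7) with multiplicative noise; ``Mean
  Intensity DAPI`` is Total/Area with noise — so the three features are
  realistically correlated, not independent.
- A G1/S-arrest phenotype (aphidicolin-like) moves mixture weight onto the
  2N mode and inflates Area (larger, flatter nuclei); a G2/M arrest
  (nocodazole-like) moves weight onto 4N and shrinks Area. The *effect
  magnitude* of a well is the absolute shift of the 2N weight.
- Plate effects are multiplicative log-normal gains per plate pass and per
  feature family (staining/exposure on intensities, optics on area), exactly
  the distortion that plate-wise median normalization corrects; replicate
  jitter adds a small per-well multiplicative wobble on top.
- Object counts per well are negative-binomial around a configurable mean.

Sample wells host siRNAs, two per gene by default. A configurable fraction
of genes carries a true arrest effect shared by both of its siRNAs
(on-target); a fraction of siRNAs is off-target and receives an independent
random effect. Positive-control wells replicate the chemical-arrest classes.

Outputs are exactly the formats :mod:`sopra.screen_io` reads (PlateList,
PlateConf_LookUp, ScreenLog, one single-cell file per plate pass) plus a
GroundTruth table; everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .screen_io import ContentType

__all__ = [
    "SimConfig",
    "FEATURES",
    "simulate_cell_table",
    "generate_screen",
    "truth_labels",
    "full_scale_config",
]

FEATURES = ["Area", "Mean Intensity DAPI", "Total Intensity DAPI"]

_G1_ARREST = "g1s_arrest"
_G2M_ARREST = "g2m_arrest"
_NULL = "null"


@dataclass
class SimConfig:
    """Screen layout, population model and noise levels of the simulator.

    Defaults are sized for desk runs: 2 plates x 96 wells x 3 replicates at
    ~500 objects per well generate in seconds; :func:`full_scale_config`
    gives an 8 x 384 x 3 preset.
    """

    n_plates: int = 2
    n_replicates: int = 3
    n_wells: int = 96
    seed: int = 0

    # objects per well: negative binomial with this mean and dispersion
    # (variance = mean + mean^2/dispersion)
    objects_mean: float = 500.0
    objects_dispersion: float = 20.0
    min_objects: int = 30

    # well layout per plate (counts; remainder of the plate is sample wells)
    n_neutral: int = 8
    n_mock: int = 2
    n_positive: int = 8  # split evenly between G1/S- and G2/M-arrest inducers
    n_flagged: int = 0

    # population model
    w_2n_control: float = 0.65  # G1 fraction of cycling controls
    mode_sigma: float = 0.18  # log-normal sigma within a DNA-content mode
    area_exponent: float = 0.7
    area_sigma: float = 0.25
    mean_sigma: float = 0.12

    # instrument limits: objects outside the Area gate are rejected by
    # segmentation; intensities saturate (clamped to the detector range).
    # Saturation is calibrated from a pilot control population at the given
    # quantiles, emulating exposure set up so the control population fills
    # the dynamic range; the segmentation gate is generous — pilot extremes
    # widened by the headroom factors — so it rejects debris and clumps, not
    # phenotypically swollen or condensed nuclei. Explicit (lo, hi) pairs in
    # `limits` override the calibration.
    limit_quantiles: tuple | None = (0.005, 0.995)
    area_gate_quantiles: tuple = (0.001, 0.999)
    area_gate_headroom: tuple = (0.7, 1.5)
    limits: dict = field(default_factory=dict)

    # effects
    sirnas_per_gene: int = 2
    frac_effect_genes: float = 0.3
    # knockdown penetrance varies between genes: each effect gene draws its
    # 2N-weight shift from this set (shared by all of its siRNAs)
    effect_magnitudes: tuple = (0.25, 0.45)
    effect_classes: tuple = (_G1_ARREST, _G2M_ARREST)
    positive_magnitude: float = 0.45
    frac_offtarget_sirnas: float = 0.0
    g1_area_gain: float = 1.8  # swollen arrested nuclei: Area scale = 1 + gain*magnitude
    g2m_area_loss: float = 1.2  # condensed mitotic nuclei: Area scale = 1 - loss*magnitude
    # G1/S arrest blocks replication before DNA doubles, so its DNA-content
    # (Total Intensity) shift is only a fraction of the nominal magnitude;
    # the morphological Area/Mean phenotype carries the full effect
    g1_dna_shift_frac: float = 0.1

    # nuisance variation
    plate_gain_sigma: float = 0.10  # per plate pass, intensities
    plate_area_sigma: float = 0.05  # per plate pass, area
    replicate_jitter_sigma: float = 0.03  # per well x replicate

    def __post_init__(self) -> None:
        reserved = self.n_neutral + self.n_mock + self.n_positive
        if reserved > self.n_wells:
            raise ValueError(
                f"layout reserves {reserved} wells but the plate has {self.n_wells}"
            )
        if self.n_neutral < 4:
            raise ValueError("every plate needs at least 4 neutral-control wells")
        if not 0 <= self.frac_effect_genes <= 1 or not 0 <= self.frac_offtarget_sirnas <= 1:
            raise ValueError("fractions must lie in [0, 1]")


def full_scale_config(seed: int = 0) -> SimConfig:
    """Preset matching a full-size screen: 8 plates x 384 wells x 3 replicates."""
    return SimConfig(n_plates=8, n_wells=384, n_replicates=3, seed=seed,
                     n_neutral=16, n_mock=4, n_positive=16)


def _design(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign content, gene/siRNA ids and true effects to every well."""
    rows = []
    pending_sirnas: list[tuple[str, str, str, float]] = []  # gene, sirna, class, magnitude

    n_sample_total = (config.n_wells - config.n_neutral - config.n_mock - config.n_positive) * config.n_plates
    n_genes = int(np.ceil(n_sample_total / config.sirnas_per_gene))
    effect_genes = rng.random(n_genes) < config.frac_effect_genes
    gene_class = rng.choice(config.effect_classes, size=n_genes)
    gene_mag = rng.choice(config.effect_magnitudes, size=n_genes)

    for g in range(n_genes):
        gene = f"GENE{g + 1:04d}"
        cls = gene_class[g] if effect_genes[g] else _NULL
        mag = float(gene_mag[g]) if effect_genes[g] else 0.0
        for s in range(config.sirnas_per_gene):
            sirna = f"si{g + 1:04d}_{s + 1}"
            if rng.random() < config.frac_offtarget_sirnas:
                # off-target siRNA: its own independent phenotype (or none)
                if rng.random() < 0.5:
                    rows_cls, rows_mag = _NULL, 0.0
                else:
                    rows_cls = str(rng.choice(config.effect_classes))
                    rows_mag = float(rng.choice(config.effect_magnitudes))
                pending_sirnas.append((gene, sirna, rows_cls, rows_mag))
            else:
                pending_sirnas.append((gene, sirna, cls, mag))

    sirna_iter = iter(pending_sirnas)
    for p in range(1, config.n_plates + 1):
        plate = f"P{p}"
        wells = list(range(1, config.n_wells + 1))
        # deterministic layout: controls first, then samples
        cursor = 0
        for _ in range(config.n_neutral):
            rows.append((plate, wells[cursor], "AllStars", ContentType.NEUTRAL_CONTROL.value,
                         None, None, _NULL, 0.0))
            cursor += 1
        for _ in range(config.n_mock):
            rows.append((plate, wells[cursor], "Mock", ContentType.MOCK.value,
                         None, None, _NULL, 0.0))
            cursor += 1
        for i in range(config.n_positive):
            if i % 2 == 0:
                label, cls = f"A{i // 2 % 4 + 1}", _G1_ARREST
            else:
                label, cls = f"N{i // 2 % 4 + 1}", _G2M_ARREST
            rows.append((plate, wells[cursor], label, ContentType.POSITIVE_CONTROL.value,
                         None, None, cls, config.positive_magnitude))
            cursor += 1
        while cursor < config.n_wells:
            try:
                gene, sirna, cls, mag = next(sirna_iter)
            except StopIteration:
                rows.append((plate, wells[cursor], "empty", ContentType.EMPTY.value,
                             None, None, _NULL, 0.0))
                cursor += 1
                continue
            rows.append((plate, wells[cursor], "sample", ContentType.SAMPLE.value,
                         sirna, gene, cls, mag))
            cursor += 1

    return pd.DataFrame(
        rows,
        columns=["plate", "well", "label", "content", "rna_id", "gene", "true_class", "magnitude"],
    )


def _draw_well(
    config: SimConfig,
    rng: np.random.Generator,
    n_obj: int,
    true_class: str,
    magnitude: float,
    gain_intensity: float,
    gain_area: float,
    jitter: float,
    limits: dict | None = None,
) -> dict[str, np.ndarray]:
    w2n = config.w_2n_control
    area_scale = 1.0
    if true_class == _G1_ARREST:
        w2n = min(0.98, w2n + config.g1_dna_shift_frac * magnitude)
        area_scale = 1.0 + config.g1_area_gain * magnitude
    elif true_class == _G2M_ARREST:
        w2n = max(0.02, w2n - magnitude)
        area_scale = max(0.3, 1.0 - config.g2m_area_loss * magnitude)
    mode = np.where(rng.random(n_obj) < w2n, 1.0, 2.0)  # 4N content = 2 x 2N
    content = mode * rng.lognormal(0.0, config.mode_sigma, n_obj)
    total = content * gain_intensity * jitter
    area = (content ** config.area_exponent) * area_scale * gain_area \
        * rng.lognormal(0.0, config.area_sigma, n_obj)
    mean = total / area * rng.lognormal(0.0, config.mean_sigma, n_obj)
    feats = {"Area": area, "Mean Intensity DAPI": mean, "Total Intensity DAPI": total}
    if limits:
        lo, hi = limits["Area"]
        keep = (area >= lo) & (area <= hi)
        feats = {name: vals[keep] for name, vals in feats.items()}
        for name in ("Mean Intensity DAPI", "Total Intensity DAPI"):
            feats[name] = np.clip(feats[name], *limits[name])
    return feats


def simulate_cell_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a screen in memory.

    Returns (cell table, ground truth). The cell table has the same layout
    as :func:`sopra.screen_io.assemble_cell_table` output; the ground truth
    has one row per (plate, well) with the true class and effect magnitude.
    """
    rng = np.random.default_rng(config.seed)
    design = _design(config, rng)
    nb_n = config.objects_dispersion
    nb_p = nb_n / (nb_n + config.objects_mean)

    # calibrate instrument limits on a pilot control population
    if config.limit_quantiles is None and not config.limits:
        limits = None
    else:
        pilot = _draw_well(config, rng, 20000, _NULL, 0.0, 1.0, 1.0, 1.0, limits=None)
        q_lo, q_hi = config.limit_quantiles or (0.0, 1.0)
        limits = {
            name: config.limits.get(name)
            or (float(np.quantile(vals, q_lo)), float(np.quantile(vals, q_hi)))
            for name, vals in pilot.items()
        }
        if "Area" not in config.limits:
            g_lo, g_hi = config.area_gate_quantiles
            h_lo, h_hi = config.area_gate_headroom
            limits["Area"] = (
                float(np.quantile(pilot["Area"], g_lo)) * h_lo,
                float(np.quantile(pilot["Area"], g_hi)) * h_hi,
            )

    parts = []
    for rep in range(1, config.n_replicates + 1):
        for plate in design["plate"].unique():
            gain_i = rng.lognormal(0.0, config.plate_gain_sigma)
            gain_a = rng.lognormal(0.0, config.plate_area_sigma)
            sub = design[design["plate"] == plate]
            for row in sub.itertuples(index=False):
                if row.content == ContentType.EMPTY.value:
                    continue
                n_obj = max(config.min_objects, int(rng.negative_binomial(nb_n, nb_p)))
                jitter = rng.lognormal(0.0, config.replicate_jitter_sigma)
                feats = _draw_well(
                    config, rng, n_obj, row.true_class, row.magnitude,
                    gain_i, gain_a, jitter, limits=limits,
                )
                part = pd.DataFrame(feats)
                part.insert(0, "plate", plate)
                part.insert(1, "replicate", rep)
                part.insert(2, "well", row.well)
                part["object"] = range(len(part))
                part["content"] = row.content
                part["rna_id"] = row.rna_id
                part["gene"] = row.gene
                part["treatment"] = row.label
                parts.append(part)
    cells = pd.concat(parts, ignore_index=True)
    truth = design[["plate", "well", "content", "rna_id", "gene", "true_class", "magnitude"]].copy()
    return cells, truth


def generate_screen(config: SimConfig, outdir: str | Path) -> pd.DataFrame:
    """Simulate a screen and write it to disk in the canonical input formats.

    Emits PlateList.txt, PlateConf_LookUp.txt, ScreenLog.txt, one single-cell
    feature file per plate pass and GroundTruth.txt. Returns the ground
    truth. Byte-identical outputs for identical configs (same seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells, truth = simulate_cell_table(config)

    plate_list = []
    for (plate, rep), sub in cells.groupby(["plate", "replicate"], sort=True):
        fname = f"{plate}_r{rep}.txt"
        sub[["well", *FEATURES]].to_csv(
            outdir / fname, sep="\t", index=False, encoding="utf-8",
            header=["Well", *FEATURES],
        )
        plate_list.append((plate, rep, fname))
    pd.DataFrame(plate_list, columns=["Plate", "Replicate", "Filename"]).to_csv(
        outdir / "PlateList.txt", sep="\t", index=False, encoding="utf-8"
    )

    design = truth.copy()
    labels = design.merge(
        cells[["plate", "well", "treatment"]].drop_duplicates(), on=["plate", "well"], how="left"
    )
    conf = pd.DataFrame(
        {
            "Plate": labels["plate"],
            "Well": labels["well"],
            "Content": labels["treatment"].fillna("empty"),
            "RNA.ID": labels["rna_id"],
            "GeneSymbol": labels["gene"],
        }
    )
    conf.to_csv(outdir / "PlateConf_LookUp.txt", sep="\t", index=False, encoding="utf-8")

    rng = np.random.default_rng(config.seed + 1)
    flags = []
    if config.n_flagged:
        candidates = truth[truth["content"] == ContentType.SAMPLE.value]
        picks = candidates.sample(
            n=min(config.n_flagged, len(candidates)), random_state=int(rng.integers(2**31))
        )
        flags = [(r.plate, r.well, "simulated flag") for r in picks.itertuples(index=False)]
    pd.DataFrame(flags, columns=["Plate", "Well", "Reason"]).to_csv(
        outdir / "ScreenLog.txt", sep="\t", index=False, encoding="utf-8"
    )

    truth.to_csv(outdir / "GroundTruth.txt", sep="\t", index=False, encoding="utf-8")
    return truth


def truth_labels(truth: pd.DataFrame, magnitude_cut: float = 0.05) -> pd.Series:
    """Boolean positive label per (plate, well): true effect above the cut."""
    labels = (truth["true_class"] != _NULL) & (truth["magnitude"] >= magnitude_cut)
    return pd.Series(labels.to_numpy(), index=pd.MultiIndex.from_frame(truth[["plate", "well"]]))
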