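"""Seeded generator of platform-compatible fixture experiments.

Emulates what a multispectral laser-scanning phenotyping platform exports:
a ZIP of CSVs with pot coordinates, ISO 8601 timestamps jittered within a
scan window of a few minutes, morphological traits following logistic
growth with factorial cultivar/treatment effects, spectral-index bins drawn
from a Dirichlet so they sum to 100%, technical replicates, and a known
fraction of planted outlier cells.  Every generated experiment carries its
ground truth (plant assignments, outlier flags, true time-point indices) so
recovery can be scored exactly.

Default design: 3 cultivars x 2 treatments x 4 replicate plants, scanned 3
times daily (8-hour spacing) over 1 day with 2 technical replicates per
scan and a 5.5-minute scan window — the cadence typical of conveyor
phenotyping protocols.  The default treatment effect is an additive shift
of two residual standard deviations, a strong but realistic stress
response.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

START_TIME = pd.Timestamp("2024-04-01 08:00:00")
POTS_PER_TABLE = 12  # pots per phenotyping table, laid out 4 x 3

MORPH_TRAITS = ("height", "leaf_area", "digital_biomass")


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design and noise model of a synthetic experiment."""

    n_cultivars: int = 3
    n_treatments: int = 2
    n_reps: int = 4
    n_scans: int = 3
    scans_per_timepoint: int = 2          # technical replicates per scan
    scan_jitter_seconds: float = 330.0    # width of one scan window
    timepoint_spacing_hours: float = 8.0  # three scans daily
    n_bins: int = 6                       # spectral-index bins (sum to 100%)
    noise_sd: float = 10.0                # residual sd of morphological traits
    treatment_effect_sd: float = 2.0      # additive shift per treatment step, in noise sds
    cultivar_effect_sd: float = 1.0       # additive shift per cultivar step, in noise sds
    bin_effect: float = 2.0               # treatment shift of Dirichlet concentration
    outlier_rate: float = 0.0
    outlier_magnitude_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_cultivars, self.n_treatments, self.n_reps,
                  self.n_scans, self.scans_per_timepoint, self.n_bins)
        if any(c < 1 for c in counts):
            raise ValidationError("all design counts must be >= 1")
        if not 0 <= self.outlier_rate < 0.1:
            raise ValidationError("outlier_rate must lie in [0, 0.1)")
        if self.scan_jitter_seconds >= self.timepoint_spacing_hours * 3600 / 2:
            raise ValidationError(
                "scan window must be narrower than half the time-point spacing"
            )

    @property
    def n_plants(self) -> int:
        return self.n_cultivars * self.n_treatments * self.n_reps

    @property
    def n_rows(self) -> int:
        return self.n_plants * self.n_scans * self.scans_per_timepoint


@dataclass
class GroundTruth:
    """What the generator actually planted, for exact recovery scoring."""

    plants: pd.DataFrame          # vtr, unit, cultivar, treatment, rep
    timepoint_index: np.ndarray   # true scan index per measurement row
    outlier_flags: pd.DataFrame   # row index x trait -> planted-outlier bool
    effects: dict = field(default_factory=dict)


def _logistic(t: np.ndarray, cap: float, rate: float, midpoint: float) -> np.ndarray:
    return cap / (1.0 + np.exp(-rate * (t - midpoint)))


def generate_tables(
    spec: DesignSpec = DesignSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Build the measurement, annotation, translation and groups tables.

    Returns ``(measurements, handmade, translation, groups, truth)`` with
    platform column conventions (``unit``, ``timestamp`` ISO strings,
    ``V.T.R`` etc.).  Fully deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)

    plants = []
    i = 0
    for c in range(spec.n_cultivars):
        cultivar = f"cv_{chr(65 + c)}"
        for t in range(spec.n_treatments):
            for r in range(spec.n_reps):
                table_no = i // POTS_PER_TABLE + 1
                pos = i % POTS_PER_TABLE
                plants.append({
                    "vtr": f"{chr(65 + c)}.{t + 1}.{r + 1}",
                    "unit": f"{table_no}:{pos % 4}:{pos // 4}",
                    "cultivar": cultivar,
                    "treatment": f"treat_{t}",
                    "cultivar_idx": c,
                    "treatment_idx": t,
                    "rep": r + 1,
                })
                i += 1
    plants = pd.DataFrame(plants)

    rows = []
    timepoint_index = []
    for scan in range(spec.n_scans):
        scan_start = START_TIME + pd.Timedelta(hours=scan * spec.timepoint_spacing_hours)
        tfrac = scan / max(spec.n_scans - 1, 1)
        for _, plant in plants.iterrows():
            for _ in range(spec.scans_per_timepoint):
                jitter = rng.uniform(0.0, spec.scan_jitter_seconds)
                ts = scan_start + pd.Timedelta(seconds=float(jitter))
                row = {"unit": plant["unit"],
                       "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f")}
                shift = spec.noise_sd * (
                    spec.treatment_effect_sd * plant["treatment_idx"]
                    + spec.cultivar_effect_sd * plant["cultivar_idx"]
                )
                for j, trait in enumerate(MORPH_TRAITS):
                    cap = 200.0 * (j + 1)
                    base = _logistic(np.array([tfrac]), cap, 6.0, 0.5)[0]
                    row[trait] = base + shift + rng.normal(0.0, spec.noise_sd)
                # spectral-index bins: Dirichlet concentrations shifted by
                # treatment on the first bin so a logit-scale effect exists
                conc = np.geomspace(8.0, 1.0, spec.n_bins).copy()
                conc[0] += spec.bin_effect * plant["treatment_idx"]
                shares = rng.dirichlet(conc) * 100.0
                for b in range(spec.n_bins):
                    row[f"ndvi_bin{b}"] = shares[b]
                rows.append(row)
                timepoint_index.append(scan)
    measurements = pd.DataFrame(rows)

    # plant outliers in morphological traits only (bins must keep their sum).
    # The planted offset is expressed in units of the within-cluster trait
    # sd — measurement noise plus the between-plant spread of the factorial
    # effects — because that pooled spread is the scale any within-cluster
    # screen operates on.
    t_idx = np.arange(spec.n_treatments)
    c_idx = np.arange(spec.n_cultivars)
    effect_var = (spec.treatment_effect_sd ** 2 * t_idx.var()
                  + spec.cultivar_effect_sd ** 2 * c_idx.var())
    cluster_sd = spec.noise_sd * float(np.sqrt(1.0 + effect_var))
    flags = pd.DataFrame(
        False, index=measurements.index, columns=list(MORPH_TRAITS)
    )
    if spec.outlier_rate > 0:
        for trait in MORPH_TRAITS:
            hit = rng.random(len(measurements)) < spec.outlier_rate
            sign = rng.choice([-1.0, 1.0], size=len(measurements))
            bump = sign * spec.outlier_magnitude_sigma * cluster_sd
            measurements.loc[hit, trait] += bump[hit]
            flags.loc[hit, trait] = True

    handmade = pd.DataFrame({
        "V.T.R": plants["vtr"],
        "Treatment": plants["treatment"],
        "Cultivar": plants["cultivar"],
    })
    translation = pd.DataFrame({"V.T.R": plants["vtr"], "T:X:Y": plants["unit"]})
    cultivars = plants[["cultivar", "cultivar_idx"]].drop_duplicates()
    groups = pd.DataFrame({
        "cultivar": cultivars["cultivar"],
        "ppd_d1": ["Ppd_D1a" if c % 2 == 0 else "Ppd_D1b"
                   for c in cultivars["cultivar_idx"]],
    })

    truth = GroundTruth(
        plants=plants,
        timepoint_index=np.asarray(timepoint_index),
        outlier_flags=flags,
        effects={
            "treatment_shift": spec.noise_sd * spec.treatment_effect_sd,
            "cultivar_shift": spec.noise_sd * spec.cultivar_effect_sd,
            "noise_sd": spec.noise_sd,
            "within_cluster_sd": cluster_sd,
        },
    )
    return measurements, handmade, translation, groups, truth


def generate_experiment(
    spec: DesignSpec, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a complete fixture project directory.

    Produces ``experiment.zip`` (measurements split over two CSVs),
    ``fixture_handmade.csv``, ``fixture_translation.csv``, ``groups.xlsx``
    and ``design.json`` (the serialized spec).  Returns the path map and
    the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements, handmade, translation, groups, truth = generate_tables(spec)

    archive = outdir / "experiment.zip"
    half = len(measurements) // 2
    with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("part_a.csv", measurements.iloc[:half].to_csv(index=False))
        zf.writestr("part_b.csv", measurements.iloc[half:].to_csv(index=False))

    paths = {
        "archive": archive,
        "handmade": outdir / "fixture_handmade.csv",
        "translation": outdir / "fixture_translation.csv",
        "groups": outdir / "groups.xlsx",
        "design": outdir / "design.json",
    }
    handmade.to_csv(paths["handmade"], index=False)
    translation.to_csv(paths["translation"], index=False)
    groups.to_excel(paths["groups"], index=False)
    paths["design"].write_text(json.dumps(dataclasses.asdict(spec), indent=2))
    return paths, truth


def worked_example_tables() -> dict[str, pd.DataFrame]:
    """Small hand-built datasets with brute-force-verifiable statistics.

    ``balanced_null``: 3x3 balanced factorial, zero effects, tiny noise —
    all F small, one shared letter.  ``dominant_treatment``: one treatment
    level shifted far from the other two — it letters alone.
    ``single_level``: a factor with one level, for the cleanup path.

    All values are fixed by hand (no random draws) so every expected
    statistic can be re-derived on paper.
    """
    out = {}

    # identical within-cell pattern for every (g1, g2) combination: all
    # group means coincide, so every factor F statistic is exactly zero
    lv = ["a", "b", "c"]
    jitter = [0.1, -0.1, 0.05, -0.05]
    rows = [{"g1": a, "g2": b, "y": 1.0 + e}
            for a in lv for b in lv for e in jitter]
    out["balanced_null"] = pd.DataFrame(rows)

    # t1 and t2 share the same mean (10.0); t3 sits 8 within-group sds away
    cell = {
        "t1": [9.8, 10.2, 10.0, 9.9, 10.1, 10.0],
        "t2": [10.1, 9.9, 10.0, 10.2, 9.8, 10.0],
        "t3": [17.8, 18.2, 18.0, 17.9, 18.1, 18.0],
    }
    out["dominant_treatment"] = pd.DataFrame(
        [{"treatment": t, "y": y} for t, ys in cell.items() for y in ys]
    )

    out["single_level"] = pd.DataFrame({
        "treatment": ["ctrl"] * 6,
        "cultivar": ["A", "A", "B", "B", "C", "C"],
        "y": [1.0, 1.2, 0.9, 1.1, 1.05, 0.95],
    })
    return out
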