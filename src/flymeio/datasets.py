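"""Packaged example datasets for the bundled assays.

The crossover class counts and foci calibration values are published
table values; the nondisjunction tallies are a *synthetic* reconstruction
— only the NDJ percentage, adjusted total and parent-female count are
published, so the diplo/nullo and female/male splits in
``ndj_tallies_synthetic.tsv`` are the (even) splits consistent with the
printed adjusted totals and one-decimal NDJ percentages.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .cytology import REGIONS
from .markers import CrossoverClassCounts, MarkerMap
from .ndj import NdjTally
from .simulate import FociCell, FociSimConfig

__all__ = [
    "data_path",
    "crossover_classes",
    "ndj_tallies",
    "chr2_marker_map",
    "chr2_interval_cm",
    "foci_calibration",
    "foci_sim_config",
]

_GENOTYPES = ("control", "cpsf5_rnai")


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("flymeio") / "data" / name)


def crossover_classes(genotype: str = "control") -> CrossoverClassCounts:
    """Published chromatid crossover-class counts for one genotype."""
    if genotype not in _GENOTYPES:
        raise ValueError(f"genotype must be one of {_GENOTYPES}")
    from .io import read_class_counts

    return read_class_counts(data_path(f"crossover_classes_{genotype}.tsv"))


def ndj_tallies() -> dict[str, NdjTally]:
    """Reconstructed (synthetic-split) NDJ tallies keyed by genotype."""
    from .io import read_ndj_tallies

    return read_ndj_tallies(data_path("ndj_tallies_synthetic.tsv"))


def _chr2_config() -> dict:
    return yaml.safe_load(data_path("marker_map_chr2.yaml").read_text())


def chr2_marker_map() -> MarkerMap:
    cfg = _chr2_config()
    return MarkerMap(chromosome_label=cfg["chromosome_label"],
                     loci=tuple(cfg["loci"]))


def chr2_interval_cm() -> tuple[float, ...]:
    """Control genetic lengths (cM) of the five chr-2 scoring intervals."""
    return tuple(float(x) for x in _chr2_config()["control_interval_cm"])


def foci_calibration() -> dict:
    """Published foci-count means/SDs/N per measure x genotype x region."""
    return yaml.safe_load(data_path("foci_calibration.yaml").read_text())


def foci_sim_config(
    measure: str = "gH2Av", seed: int = 0, n_override: int | None = None
) -> FociSimConfig:
    """Generator config calibrated to the packaged moments for one measure."""
    calib = foci_calibration()
    if measure not in calib:
        raise ValueError(f"measure must be one of {sorted(calib)}")
    cells = []
    for genotype, regions in calib[measure].items():
        for region, m in regions.items():
            if region not in REGIONS:
                raise ValueError(f"bad region {region!r} in calibration")
            cells.append(
                FociCell(
                    genotype=genotype,
                    region=region,
                    mean=float(m["mean"]),
                    sd=float(m["sd"]),
                    n_nuclei=int(n_override or m["n"]),
                    measure=measure,
                )
            )
    return FociSimConfig(cells=tuple(cells), seed=seed)
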