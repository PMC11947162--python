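"""Configuration dataclasses for the simulator and imaging model.

All lengths are in µm, all times in minutes. Coordinates follow the image
convention: origin at the field corner, y increasing downward.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "Modifiers",
    "SimulationConfig",
    "ImagingConfig",
    "GUVPairConfig",
    "LipidSpecies",
    "LipidSimConfig",
]


@dataclass
class Modifiers:
    """Perturbation switches applied to the propagation step.

    fer1_time / fer1_efficacy
        From ``fer1_time`` onward the per-contact conversion probability is
        multiplied by ``fer1_efficacy`` (0 = complete radical-trapping block,
        1 = no effect). ``None`` disables the treatment.
    iron_factor
        Multiplier in [0, 1] modelling extracellular iron chelation (DFO);
        0 abolishes contact conversion.
    contacts_enabled
        ``False`` removes the contact channel entirely (α-catenin loss /
        calcium-free medium: cells no longer touch effectively).
    bilayer_range
        If set, newly dead cells additionally expose *non-contact* cells up
        to this distance, with linearly decaying probability (lipid-bilayer
        bridge experiments). ``None`` disables it.
    draq7_lag
        Minutes between morphological death (blebbing) and DRAQ7 positivity
        (membrane permeabilisation).
    """

    fer1_time: Optional[float] = None
    fer1_efficacy: float = 0.1
    iron_factor: float = 1.0
    contacts_enabled: bool = True
    bilayer_range: Optional[float] = None
    draq7_lag: float = 4.0

    def validate(self) -> None:
        if self.fer1_time is not None and self.fer1_time < 0:
            raise ValueError("fer1_time must be >= 0 or None")
        if not 0.0 <= self.fer1_efficacy <= 1.0:
            raise ValueError("fer1_efficacy must be in [0, 1]")
        if not 0.0 <= self.iron_factor <= 1.0:
            raise ValueError("iron_factor must be in [0, 1]")
        if self.bilayer_range is not None and self.bilayer_range <= 0:
            raise ValueError("bilayer_range must be > 0 or None")
        if self.draq7_lag < 0:
            raise ValueError("draq7_lag must be >= 0")


@dataclass
class SimulationConfig:
    """Conditions for one monolayer / propagation experiment.

    Defaults describe a 500 µm confluent HeLa field with ten opto-activated
    cells observed for 12 h at a 2-min clock. Activated cells die with
    truncated-normal timing (mean 17 min, range 13–20 min); bystander
    conversion follows a per-contact chain-binomial with probability
    ``p_spread`` per newly dead neighbour per step.
    """

    field_size: float = 500.0
    target_confluency: float = 0.5
    diameter_mean: float = 23.0
    diameter_sd: float = 2.0
    transfected_fraction: float = 0.3
    n_illuminated: int = 10
    t_end: float = 720.0
    dt: float = 2.0
    opto_death_mean: float = 17.0
    opto_death_sd: float = 2.0
    opto_death_min: float = 13.0
    opto_death_max: float = 20.0
    onset_delay_meanlog: float = math.log(30.0)
    onset_delay_sdlog: float = 0.4
    onset_to_death_mean: float = 60.0
    onset_to_death_sd: float = 15.0
    p_spread: float = 0.4
    background_hazard: float = 1e-5
    overlap_tolerance: float = 0.1
    modifiers: Modifiers = field(default_factory=Modifiers)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.target_confluency <= 1.0:
            raise ValueError("target_confluency must be in (0, 1]")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be > 0")
        if self.diameter_sd < 0:
            raise ValueError("diameter_sd must be >= 0")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must be in [0, 1]")
        if self.n_illuminated < 0:
            raise ValueError("n_illuminated must be >= 0")
        for name in ("t_end", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        n_steps = self.t_end / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt must divide t_end")
        if not (self.opto_death_min <= self.opto_death_mean <= self.opto_death_max):
            raise ValueError("require opto_death_min <= opto_death_mean <= opto_death_max")
        if self.opto_death_min < 0 or self.opto_death_sd < 0:
            raise ValueError("opto death parameters must be non-negative")
        if self.onset_delay_sdlog < 0 or self.onset_to_death_sd < 0:
            raise ValueError("delay spreads must be >= 0")
        if self.onset_to_death_mean < 0:
            raise ValueError("onset_to_death_mean must be >= 0")
        if not 0.0 <= self.p_spread <= 1.0:
            raise ValueError("p_spread must be in [0, 1]")
        if not 0.0 <= self.background_hazard <= 1.0:
            raise ValueError("background_hazard must be a per-minute probability in [0, 1]")
        if not 0.0 <= self.overlap_tolerance < 1.0:
            raise ValueError("overlap_tolerance must be in [0, 1)")
        self.modifiers.validate()

    # --- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        mods = d.pop("modifiers", {})
        cfg = cls(**d, modifiers=Modifiers(**mods) if isinstance(mods, dict) else mods)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML or JSON file (decided by extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ImagingConfig:
    """Virtual-microscope settings used by :func:`render_frames`.

    Channel gains/offsets are arbitrary intensity units; noise is additive
    Gaussian per pixel. ``ox_rise_minutes`` is the time over which the
    BODIPY green/red balance of an oxidising cell ramps from fully reduced
    to fully oxidised.
    """

    pixel_size: float = 1.0
    frame_interval: float = 6.0
    psf_sigma: float = 1.0
    gains: dict = field(
        default_factory=lambda: {
            "marker": 120.0,
            "draq7": 150.0,
            "bodipy_green": 100.0,
            "bodipy_red": 100.0,
        }
    )
    offsets: dict = field(
        default_factory=lambda: {
            "marker": 10.0,
            "draq7": 10.0,
            "bodipy_green": 10.0,
            "bodipy_red": 10.0,
        }
    )
    noise_sd: float = 3.0
    ox_rise_minutes: float = 20.0
    seed: int = 0

    CHANNELS = ("marker", "draq7", "bodipy_green", "bodipy_red")

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        for ch in self.CHANNELS:
            if ch not in self.gains or ch not in self.offsets:
                raise ValueError(f"missing gain/offset for channel {ch!r}")


@dataclass
class GUVPairConfig:
    """Donor/acceptor giant-unilamellar-vesicle transfer model.

    The donor oxidises at rate ``k_act`` (photosensitised); the acceptor
    oxidises at rate ``k0 * iron_conc * x_donor`` only while in membrane
    contact. Measured ratios map the oxidised fraction x through
    ``baseline_ratio + (1 - baseline_ratio) * x``.
    """

    k_act: float = 0.08
    k0: float = 0.5
    iron_conc: float = 0.5
    contact: bool = True
    baseline_ratio: float = 0.2
    dt: float = 0.5
    t_end: float = 60.0

    def validate(self) -> None:
        if self.k_act < 0 or self.k0 < 0 or self.iron_conc < 0:
            raise ValueError("rates and concentrations must be >= 0")
        if not 0.0 <= self.baseline_ratio < 1.0:
            raise ValueError("baseline_ratio must be in [0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")


@dataclass
class LipidSpecies:
    """One simulated lipid species: its true illuminated/control fold change,
    a control-condition normalised level, and the internal standard it maps to."""

    name: str
    true_fold_change: float
    base_level: float = 1.0
    standard: str = "IS"


@dataclass
class LipidSimConfig:
    """Ground-truth design for a peak-area table with internal standards."""

    species: list = field(
        default_factory=lambda: [
            LipidSpecies("PC(16:0/18:1)+2O", 3.0, standard="IS_PC"),
            LipidSpecies("PE(18:0/20:4)+3O", 5.0, standard="IS_PE"),
            LipidSpecies("PC(16:0/18:2)", 1.0, standard="IS_PC"),
        ]
    )
    standard_areas: dict = field(default_factory=lambda: {"IS_PC": 2.0e5, "IS_PE": 1.5e5, "IS": 1.0e5})
    protein_ug: float = 50.0
    n_replicates: int = 3
    cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.protein_ug <= 0:
            raise ValueError("protein_ug must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sp in self.species:
            if sp.true_fold_change <= 0 or sp.base_level <= 0:
                raise ValueError(f"species {sp.name!r}: fold change and base level must be > 0")
            if sp.standard not in self.standard_areas:
                raise ValueError(f"species {sp.name!r}: unknown standard {sp.standard!r}")
        for k, v in self.standard_areas.items():
            if v <= 0:
                raise ValueError(f"standard {k!r} area must be > 0")
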