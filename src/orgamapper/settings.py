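"""Analysis settings and their XML (de)serialization.

Every run of the pipeline is controlled by a :class:`Settings` object that
bundles segmentation, detection and data-analysis parameters together with the
pixel size and the channel-role mapping.  Settings round-trip losslessly
through a flat key-value XML document so that a run can be reproduced from the
settings file copied into its output directory.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree as ET

__all__ = [
    "SegmentationSettings",
    "DetectionSettings",
    "AnalysisSettings",
    "Settings",
    "read_settings",
    "write_settings",
]


@dataclass
class SegmentationSettings:
    """Parameters of nucleus and single-cell segmentation.

    Nuclei: median filter -> rolling-ball background subtraction -> automatic
    global threshold -> optional erosions -> size/circularity/border filter.
    Cells: (optional channel inversion) -> median -> rolling ball -> fixed
    threshold -> marker-controlled watershed -> size/circularity/nucleus-count
    filter.  A radius of 0 disables the corresponding filter step.

    Size ranges are in square micrometres, circularity (4*pi*A/P^2) in [0, 1].
    Numeric defaults are starting points for clean, high-contrast data and are
    expected to be tuned per dataset.
    """

    nucleus_median_radius: int = 2
    nucleus_rolling_ball_radius: int = 0
    nucleus_threshold_method: str = "otsu"
    nucleus_erosion_count: int = 0
    nucleus_size_range: tuple[float, float] = (100.0, 1e5)
    nucleus_circularity_range: tuple[float, float] = (0.0, 1.0)
    cell_median_radius: int = 2
    cell_rolling_ball_radius: int = 0
    cell_fixed_threshold: float = 60.0
    watershed_gaussian_sigma: float = 10.0
    watershed_maxima_prominence: float = 10.0
    cell_size_range: tuple[float, float] = (100.0, 1e6)
    cell_circularity_range: tuple[float, float] = (0.0, 1.0)
    invert_cytoplasm_channel: bool = False
    reject_border_cells: bool = False

    def __post_init__(self) -> None:
        for name in ("nucleus_size_range", "nucleus_circularity_range",
                     "cell_size_range", "cell_circularity_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        for name in ("nucleus_circularity_range", "cell_circularity_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi > 1:
                raise ValueError(f"{name} must lie within [0, 1]")


@dataclass
class DetectionSettings:
    """Laplacian-of-Gaussian spot detection parameters.

    ``log_sigma`` selects the organelle size (optimal for blobs of radius
    ~ sqrt(2)*sigma); ``prominence`` is the minimum height of a maximum of the
    scale-normalized LoG response above its highest connecting saddle.
    Detections inside the nucleus mask are discarded when
    ``exclude_in_nucleus`` is set.
    """

    log_sigma: float = 2.0
    prominence: float = 100.0
    exclude_in_nucleus: bool = True

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be > 0")
        if self.prominence < 0:
            raise ValueError("prominence must be >= 0")


@dataclass
class AnalysisSettings:
    """Downstream data-analysis parameters (micrometre units)."""

    background_subtract: bool = True
    cell_diameter_max: float = 600.0
    perinuclear_perimeter: float = 10.0
    density_bandwidth: float | str = "auto"
    intensity_bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.cell_diameter_max <= 0 or self.perinuclear_perimeter <= 0:
            raise ValueError("cell_diameter_max and perinuclear_perimeter must be > 0")
        if self.intensity_bin_width <= 0:
            raise ValueError("intensity_bin_width must be > 0")
        if not (self.density_bandwidth == "auto"
                or (isinstance(self.density_bandwidth, (int, float))
                    and self.density_bandwidth > 0)):
            raise ValueError("density_bandwidth must be 'auto' or a positive number")


_DEFAULT_ROLES = {"nucleus": 0, "cytoplasm": 1, "organelle": 2}


@dataclass
class Settings:
    """Complete, serializable configuration of one analysis run."""

    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    pixel_size: float = 1.0
    channel_roles: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ROLES))
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        missing = {"nucleus", "cytoplasm", "organelle"} - set(self.channel_roles)
        if missing:
            raise ValueError(f"channel_roles missing required roles: {sorted(missing)}")


def _format(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, tuple):
        return ",".join(repr(float(v)) for v in value)
    return str(value)


def _parse(text: str, template):
    if isinstance(template, bool):
        if text not in ("true", "false"):
            raise ValueError(f"expected boolean, got {text!r}")
        return text == "true"
    if isinstance(template, tuple):
        parts = text.split(",")
        return tuple(float(p) for p in parts)
    if isinstance(template, int) and not isinstance(template, bool):
        return int(text)
    if isinstance(template, float):
        return float(text)
    if isinstance(template, str):
        # density_bandwidth may be "auto" or numeric
        try:
            return float(text)
        except ValueError:
            return text
    return text


def _flatten(settings: Settings) -> dict[str, str]:
    out: dict[str, str] = {"pixel_size": _format(settings.pixel_size)}
    for role, idx in sorted(settings.channel_roles.items()):
        out[f"channel.{role}"] = str(idx)
    for section in ("segmentation", "detection", "analysis"):
        obj = getattr(settings, section)
        for f in dataclasses.fields(obj):
            out[f"{section}.{f.name}"] = _format(getattr(obj, f.name))
    out.update(settings.extra)
    return out


def write_settings(settings: Settings, path: str | Path) -> Path:
    """Serialize *settings* to a flat key-value XML file."""
    root = ET.Element("orgamapper_settings", version="1")
    for key, value in _flatten(settings).items():
        el = ET.SubElement(root, "setting", name=key)
        el.text = value
    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path


def read_settings(path: str | Path) -> Settings:
    """Parse a settings XML file written by :func:`write_settings`.

    Raises ``KeyError`` naming the first missing required key; unknown keys
    are preserved in ``Settings.extra`` with a warning.
    """
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed settings XML in {path}: {exc}") from exc
    entries: dict[str, str] = {}
    for el in root.iter("setting"):
        entries[el.attrib["name"]] = el.text or ""

    defaults = Settings()
    kwargs: dict = {}
    if "pixel_size" not in entries:
        raise KeyError("settings file is missing required key 'pixel_size'")
    kwargs["pixel_size"] = float(entries.pop("pixel_size"))

    roles = {}
    for key in [k for k in entries if k.startswith("channel.")]:
        roles[key.split(".", 1)[1]] = int(entries.pop(key))
    for role in ("nucleus", "cytoplasm", "organelle"):
        if role not in roles:
            raise KeyError(f"settings file is missing required key 'channel.{role}'")
    kwargs["channel_roles"] = roles

    for section, cls in (("segmentation", SegmentationSettings),
                         ("detection", DetectionSettings),
                         ("analysis", AnalysisSettings)):
        section_defaults = getattr(defaults, section)
        section_kwargs = {}
        for f in dataclasses.fields(cls):
            key = f"{section}.{f.name}"
            if key not in entries:
                raise KeyError(f"settings file is missing required key '{key}'")
            section_kwargs[f.name] = _parse(entries.pop(key),
                                            getattr(section_defaults, f.name))
        kwargs[section] = cls(**section_kwargs)

    if entries:
        warnings.warn(f"settings file contains unknown keys (preserved): {sorted(entries)}",
                      stacklevel=2)
    kwargs["extra"] = dict(entries)
    return Settings(**kwargs)
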