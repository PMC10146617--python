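"""Functional-network definitions.

A network is an ordered list of regions of interest (ROIs).  The order is
significant: region ``i`` of a network maps to bit ``i`` of the integer
codes used for binary activity patterns, so two analyses are only
comparable when they use the same region order.

Defaults are loaded from the ``networks.yaml`` data file shipped with the
package; users may supply their own YAML with the same layout (e.g. to add
a default-mode network, which has no constituent list in the default
atlas).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

MIN_REGIONS = 2
MAX_REGIONS = 12

KNOWN_NETWORK_NAMES = (
    "sensorimotor",
    "auditory",
    "default_mode",
    "visual",
    "frontoparietal",
    "salience",
    "attention",
)


@dataclass(frozen=True)
class NetworkDefinition:
    """An ordered set of ROI names making up one functional network."""

    name: str
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        object.__setattr__(self, "regions", regions)
        if not (MIN_REGIONS <= len(regions) <= MAX_REGIONS):
            raise ValueError(
                f"network {self.name!r} has {len(regions)} regions; "
                f"expected between {MIN_REGIONS} and {MAX_REGIONS}"
            )
        if len(set(regions)) != len(regions):
            raise ValueError(f"network {self.name!r} has duplicate region names")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index(self, region: str) -> int:
        return self.regions.index(region)


def networks_from_mapping(mapping: dict) -> dict[str, NetworkDefinition]:
    """Build :class:`NetworkDefinition` objects from a name -> regions map."""
    return {
        name: NetworkDefinition(name=name, regions=tuple(regions))
        for name, regions in mapping.items()
    }


def load_networks(path) -> dict[str, NetworkDefinition]:
    """Load network definitions from a YAML file (name -> list of ROIs)."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict) or not mapping:
        raise ValueError(f"{path}: expected a non-empty mapping of network -> regions")
    return networks_from_mapping(mapping)


def default_networks() -> dict[str, NetworkDefinition]:
    """The six packaged network definitions (sensorimotor, visual, auditory,
    frontoparietal, salience, attention)."""
    ref = resources.files("tmslandscape").joinpath("data/networks.yaml")
    mapping = yaml.safe_load(ref.read_text())
    return networks_from_mapping(mapping)


def all_regions(networks: dict[str, NetworkDefinition]) -> tuple[str, ...]:
    """Distinct ROI names across *networks*, in first-appearance order."""
    seen: list[str] = []
    for net in networks.values():
        for region in net.regions:
            if region not in seen:
                seen.append(region)
    return tuple(seen)
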