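"""Standard network fixtures and config-file loading.

Networks can be declared in YAML/JSON configs (variables, links with
polarity); the package ships the structures used across the causal
reasoning literature this model addresses: the three-variable common
cause, chain and common-effect networks, a common cause with one
inhibitory link, and the three four-variable diamond conditions
(Generative, YA-Inhibitory, YB-Inhibitory).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .networks import CausalNetwork

__all__ = [
    "CONDITIONS",
    "CONDITION_NETWORKS",
    "load_network",
    "load_networks_config",
    "network_for_condition",
]

#: Between-subject condition labels, in reporting order.
CONDITIONS = ("Generative", "YA-Inhibitory", "YB-Inhibitory")

#: Condition label -> fixture name of the diamond network it uses.
CONDITION_NETWORKS = {
    "Generative": "diamond_generative",
    "YA-Inhibitory": "diamond_ya_inhibitory",
    "YB-Inhibitory": "diamond_yb_inhibitory",
}


def _parse_network(spec: dict) -> CausalNetwork:
    return CausalNetwork(
        variables=tuple(spec["variables"]),
        links=tuple((s, t, p) for s, t, p in spec["links"]),
    )


def load_networks_config(path: str | Path | None = None) -> dict[str, CausalNetwork]:
    """Load a {name: network} mapping from a YAML/JSON config file.

    With no path, loads the fixtures shipped with the package.
    """
    if path is None:
        text = (
            resources.files("mutsampler") / "configs" / "networks.yaml"
        ).read_text()
        data = yaml.safe_load(text)
    else:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    return {name: _parse_network(spec) for name, spec in data["networks"].items()}


def load_network(name: str, path: str | Path | None = None) -> CausalNetwork:
    """Load one named network from a config (default: shipped fixtures)."""
    networks = load_networks_config(path)
    try:
        return networks[name]
    except KeyError:
        raise KeyError(
            f"unknown network {name!r}; available: {sorted(networks)}"
        ) from None


def network_for_condition(condition: str) -> CausalNetwork:
    """The diamond network of a between-subject condition label."""
    try:
        return load_network(CONDITION_NETWORKS[condition])
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        ) from None
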