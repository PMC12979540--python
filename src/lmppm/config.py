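"""YAML configuration resolution, graph serialisation and run manifests.

Precedence is command line > YAML file > built-in defaults.  Unknown YAML
keys are rejected by name, so typos fail loudly instead of silently falling
back to defaults.  Every CLI subcommand records a :class:`RunManifest`
(resolved config, seeds, package version, SHA-256 of each emitted artifact)
next to its outputs; deterministic commands are hash-reproducible from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .graph import LayerDescriptor, LayerGraph

__all__ = ["ConfigError", "resolve_config", "RunManifest",
           "save_graph_yaml", "load_graph_yaml", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Bad configuration input (unknown key, malformed YAML)."""


def resolve_config(defaults: dict, yaml_path: str | Path | None = None,
                   overrides: dict | None = None) -> dict:
    """Merge defaults < YAML file < explicit overrides (None = unset)."""
    out = dict(defaults)
    if yaml_path is not None:
        try:
            loaded = yaml.safe_load(Path(yaml_path).read_text())
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            where = f" line {mark.line + 1}" if mark else ""
            raise ConfigError(f"malformed YAML in {yaml_path}{where}: {e}")
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{yaml_path}: top level must be a mapping")
        unknown = sorted(set(loaded) - set(defaults))
        if unknown:
            raise ConfigError(
                f"unknown config key(s) in {yaml_path}: {', '.join(unknown)}")
        out.update(loaded)
    for k, v in (overrides or {}).items():
        if k not in defaults:
            raise ConfigError(f"unknown config key: {k}")
        if v is not None:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    schema_version: int = SCHEMA_VERSION

    def record_output(self, path: str | Path) -> None:
        p = Path(path)
        if p.is_file():
            self.outputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        from importlib.metadata import version, PackageNotFoundError
        try:
            ver = version("lmppm")
        except PackageNotFoundError:  # pragma: no cover
            ver = "unknown"
        doc = {"command": self.command, "config": self.config,
               "seeds": self.seeds, "inputs": self.inputs,
               "outputs": self.outputs, "package_version": ver,
               "schema_version": self.schema_version}
        Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")


# --------------------------------------------------------------------------
# graph YAML
# --------------------------------------------------------------------------

def save_graph_yaml(g: LayerGraph, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": g.name,
        "entry": g.entry, "exit": g.exit,
        "input_size": g.input_size, "num_classes": g.num_classes,
        "classifier": g.classifier, "stem_ids": list(g.stem_ids),
        "head_start": g.head_start,
        "layers": [l.to_dict() for l in g.layers.values()],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_graph_yaml(path: str | Path) -> LayerGraph:
    doc = yaml.safe_load(Path(path).read_text())
    layers = [LayerDescriptor(**d) for d in doc["layers"]]
    g = LayerGraph.from_layers(
        layers, input_size=doc["input_size"], num_classes=doc["num_classes"],
        classifier=doc.get("classifier"), stem_ids=doc.get("stem_ids", []),
        head_start=doc.get("head_start"), name=doc.get("name", "graph"))
    g.entry, g.exit = doc["entry"], doc["exit"]
    g.validate()
    return g
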