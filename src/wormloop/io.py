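"""Reading and writing circuit configuration documents.

A circuit is stored as one human-readable YAML document with sections
``neurons``, ``muscles``, ``synapses``, ``gap_junctions``, ``feedbacks`` and
``inputs`` (external currents, split out of the neuron records so triggers
are visible at a glance).  Potentials are mV, lengths um, time s.  The
resolved wiring can also be exported as JSON or GraphML for inspection.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import yaml

from .circuit import (
    ChemicalSynapse,
    CircuitConfig,
    FeedbackConnection,
    GapJunction,
    MuscleSpec,
    NeuronSpec,
)
from .errors import ConfigurationError


def config_to_dict(config: CircuitConfig) -> dict:
    """Plain-data representation used by both YAML and JSON export."""
    neurons = []
    inputs = {}
    for n in config.neurons:
        d = dataclasses.asdict(n)
        i_ext = d.pop("i_external")
        if i_ext != 0.0:
            inputs[n.id] = i_ext
        neurons.append(d)
    return {
        "circuit": {"name": config.name, "E_Ca": config.e_ca, "E_K": config.e_k},
        "neurons": neurons,
        "muscles": [dataclasses.asdict(m) for m in config.muscles],
        "synapses": [dataclasses.asdict(s) for s in config.chemical_synapses],
        "gap_junctions": [dataclasses.asdict(g) for g in config.gap_junctions],
        "feedbacks": [dataclasses.asdict(f) for f in config.feedbacks],
        "inputs": inputs,
    }


def config_from_dict(doc: dict) -> CircuitConfig:
    try:
        head = doc["circuit"]
        inputs = doc.get("inputs", {})
        neurons = [
            NeuronSpec(**{**d, "i_external": float(inputs.get(d["id"], 0.0))})
            for d in doc["neurons"]
        ]
        cfg = CircuitConfig(
            name=head["name"],
            neurons=neurons,
            muscles=[MuscleSpec(**d) for d in doc["muscles"]],
            chemical_synapses=[ChemicalSynapse(**d) for d in doc["synapses"]],
            gap_junctions=[GapJunction(**d) for d in doc["gap_junctions"]],
            feedbacks=[FeedbackConnection(**d) for d in doc["feedbacks"]],
            e_ca=float(head["E_Ca"]),
            e_k=float(head["E_K"]),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed circuit document: {exc}") from exc
    return cfg.validate()


def dumps_config(config: CircuitConfig) -> str:
    header = (
        "# wormloop circuit configuration\n"
        "# units: potentials mV, currents mV*conductance-unit, lengths um, time s\n"
    )
    return header + yaml.safe_dump(
        config_to_dict(config), sort_keys=False, default_flow_style=False
    )


def loads_config(text: str) -> CircuitConfig:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("circuit document is not a mapping")
    return config_from_dict(doc)


def save_config(config: CircuitConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dumps_config(config))
    return path


def load_config(path: str | Path) -> CircuitConfig:
    return loads_config(Path(path).read_text())


def config_to_json(config: CircuitConfig, path: str | Path | None = None) -> str:
    text = json.dumps(config_to_dict(config), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_to_graph(config: CircuitConfig) -> nx.MultiDiGraph:
    """Resolved wiring as a networkx graph (gap junctions appear once,
    flagged undirected)."""
    g = nx.MultiDiGraph(name=config.name)
    for n in config.neurons:
        g.add_node(n.id, node_type="neuron", neuron_class=n.neuron_class,
                   side=n.side, unit=-1 if n.unit_index is None else n.unit_index)
    for m in config.muscles:
        g.add_node(m.id, node_type="muscle", side=m.side, unit=m.unit_index)
    for s in config.chemical_synapses:
        g.add_edge(s.pre, s.post, kind="chemical", weight=s.weight,
                   reversal=s.reversal)
    for gj in config.gap_junctions:
        g.add_edge(gj.a, gj.b, kind="gap", weight=gj.weight, undirected=True)
    for f in config.feedbacks:
        g.add_edge(f.source_muscle, f.target_neuron, kind="feedback",
                   weight=f.weight, polarity=f.polarity)
    return g


def export_graphml(config: CircuitConfig, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(config_to_graph(config), path)
    return path
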