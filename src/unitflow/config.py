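"""JSON system configurations.

A config describes a complete run: either a packaged example,

    {"example": {"name": "example2", "seed": 0, "relax_time": 30.0}}

or a fully explicit system:

    {
      "coordinates": [{"name": "1", "size": 2}, ...],
      "reservoirs": [
        {"name": "r1", "puppets": ["1"], "leaders": ["1", "2"],
         "rates": {"mode": "explicit", "table": [[...], ...]}
         # or {"mode": "random", "seed": 7, "scale": 1.0}
        }, ...
      ],
      "units": [["1", "2"], ["2"], ...],
      "initial": {"mode": "uniform" | "delta" | "random" | "explicit", ...},
      "time": {"ti": 0.0, "tf": 5.0, "n_grid": 201},
      "protocol": [{"t0": 0.0, "t1": 2.5, "scale": 1.0}, ...]   # optional
    }

The optional ``protocol`` applies a piecewise-constant scale factor to every
explicit/random rate table.  Explicit tables are compact ``(n_puppet,
n_leader)`` matrices in the package's flat sub-space enumeration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import fixtures
from .fixtures import FixtureBundle, _random_table
from .reservoirs import CompositeSystem, ConstantRates, PiecewiseRates, Reservoir
from .statespace import Coordinate, Distribution, JointSpace
from .structures import UnitStructure

__all__ = ["load_config", "RunConfig"]

_EXAMPLES = {
    "fig1": fixtures.build_fig1,
    "example2": fixtures.build_example2,
    "walker": fixtures.build_walker,
}


@dataclass
class RunConfig:
    bundle: FixtureBundle
    n_grid: int = 201


def _config_error(msg: str) -> ValueError:
    return ValueError(f"config error: {msg}")


def load_config(source) -> RunConfig:
    """Parse a config mapping, JSON string, or path into a runnable bundle."""
    if isinstance(source, dict):
        cfg = source
    elif isinstance(source, (str, Path)) and Path(str(source)).exists():
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = json.loads(source)

    time_cfg = cfg.get("time", {})
    n_grid = int(time_cfg.get("n_grid", 201))

    if "example" in cfg:
        ex = dict(cfg["example"])
        name = ex.pop("name", None)
        if name not in _EXAMPLES:
            raise _config_error(
                f"unknown example {name!r}; choose from {sorted(_EXAMPLES)}"
            )
        bundle = _EXAMPLES[name](**ex)
        if "tf" in time_cfg:
            bundle.tf = float(time_cfg["tf"])
        return RunConfig(bundle=bundle, n_grid=n_grid)

    for key in ("coordinates", "reservoirs", "units"):
        if key not in cfg:
            raise _config_error(f"missing required key {key!r}")

    coords = []
    for c in cfg["coordinates"]:
        try:
            coords.append(Coordinate(str(c["name"]), int(c["size"])))
        except (KeyError, TypeError) as exc:
            raise _config_error(f"bad coordinate entry {c!r}: {exc}") from exc
    space = JointSpace(coords)

    segments = cfg.get("protocol")
    reservoirs = []
    for r in cfg["reservoirs"]:
        try:
            name = str(r["name"])
            puppets = [str(p) for p in r["puppets"]]
            leaders = [str(p) for p in r["leaders"]]
            rates = r["rates"]
            mode = rates["mode"]
        except (KeyError, TypeError) as exc:
            raise _config_error(f"bad reservoir entry {r!r}: {exc}") from exc
        if mode == "explicit":
            table = np.asarray(rates["table"], dtype=float)
        elif mode == "random":
            rng = np.random.default_rng(int(rates.get("seed", 0)))
            table = _random_table(rng, space, puppets, leaders,
                                  float(rates.get("scale", 1.0)))
        else:
            raise _config_error(
                f"reservoir {name!r}: unknown rates mode {mode!r}"
            )
        if segments:
            proto = PiecewiseRates([
                (float(s["t0"]), float(s["t1"]), float(s["scale"]) * table)
                for s in segments
            ])
        else:
            proto = ConstantRates(table)
        reservoirs.append(Reservoir(name, puppets, leaders, proto))

    system = CompositeSystem(space, reservoirs)
    structure = UnitStructure(
        [frozenset(map(str, u)) for u in cfg["units"]],
        allow_full=bool(cfg.get("allow_full", False)),
    )

    init_cfg = cfg.get("initial", {"mode": "uniform"})
    mode = init_cfg.get("mode", "uniform")
    if mode == "uniform":
        p0 = np.full(space.size, 1.0 / space.size)
    elif mode == "delta":
        p0 = np.zeros(space.size)
        p0[space.index(tuple(int(v) for v in init_cfg["state"]))] = 1.0
    elif mode == "random":
        rng = np.random.default_rng(int(init_cfg.get("seed", 0)))
        p0 = rng.dirichlet(np.ones(space.size))
    elif mode == "explicit":
        p0 = np.asarray(init_cfg["probabilities"], dtype=float)
    else:
        raise _config_error(f"unknown initial mode {mode!r}")
    initial = Distribution(space, p0, renormalize=bool(
        init_cfg.get("renormalize", False)))

    ti = float(time_cfg.get("ti", 0.0))
    tf = float(time_cfg.get("tf", 1.0))
    bundle = FixtureBundle("config", system, structure, initial, ti, tf)
    return RunConfig(bundle=bundle, n_grid=n_grid)
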