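"""Run configuration, state serialization and run manifests.

Configurations are YAML mappings with a strict schema: unknown keys are
fatal and validation errors name the offending key, so that a typo in a
parameter name cannot silently fall back to a default.  Snapshots are
written to an HDF5 container with one group per species (datasets ``N``
and ``B`` for the continuous model, the occupancy grid plus per-species
``B`` for the lattice model) and enough attributes to identify the model,
the time stamp, and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .ca import CAParameters, Lattice, ToxinFields
from .networks import InteractionNetwork, build_cycle, read_matrix_file
from .pde import ContinuousParameters, FieldState, GridSpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "parse_config",
    "save_state",
    "load_state",
    "write_manifest",
]


class ConfigError(ValueError):
    """Configuration failed validation; the message names the key."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    ``params`` is a :class:`ContinuousParameters` (``model="pde"``) or
    :class:`CAParameters` (``model="ca"``); ``init`` and ``run`` are plain
    dicts of validated, default-filled values.  ``seed`` is the master seed
    from which every stochastic stream is derived.
    """

    model: str
    network: InteractionNetwork
    params: object
    grid: GridSpec | None
    init: dict
    run: dict
    output: str
    seed: int | None
    raw: dict

    def seed_sequences(self, override: int | None = None):
        """Spawn independent child seeds (init, dynamics) from the master
        seed so that unrelated settings cannot perturb the dynamics."""
        seed = override if override is not None else self.seed
        ss = np.random.SeedSequence(seed)
        init_ss, dyn_ss = ss.spawn(2)
        return init_ss, dyn_ss


def _require_mapping(block, key: str) -> dict:
    if block is None:
        return {}
    if not isinstance(block, dict):
        raise ConfigError(f"`{key}` must be a mapping")
    return dict(block)


def _check_unknown(block: dict, allowed: set, where: str) -> None:
    for k in block:
        if k not in allowed:
            raise ConfigError(f"unknown key `{where}{k}`")


def _pop(block: dict, key: str, default, where: str, kind=None):
    val = block.pop(key, default)
    if val is not None and kind is not None and not isinstance(val, kind):
        # bool is an int subclass; reject it for numeric fields
        if not (kind is float and isinstance(val, int) and not isinstance(val, bool)):
            raise ConfigError(f"`{where}{key}` has wrong type {type(val).__name__}")
    return val


def _build_network(block, n_species_hint=None) -> InteractionNetwork:
    block = _require_mapping(block, "network")
    _check_unknown(block, {"cycle", "matrix_file"}, "network.")
    if ("cycle" in block) == ("matrix_file" in block):
        raise ConfigError("`network` needs exactly one of `cycle` or `matrix_file`")
    if "cycle" in block:
        cyc = _require_mapping(block["cycle"], "network.cycle")
        _check_unknown(cyc, {"n", "out_degree"}, "network.cycle.")
        n = cyc.get("n", n_species_hint)
        if n is None:
            raise ConfigError("missing key `network.cycle.n`")
        try:
            return build_cycle(int(n), int(cyc.get("out_degree", 1)))
        except ValueError as exc:
            raise ConfigError(f"invalid `network.cycle`: {exc}") from exc
    try:
        return read_matrix_file(block["matrix_file"])
    except (OSError, ValueError) as exc:
        raise ConfigError(f"invalid `network.matrix_file`: {exc}") from exc


_PDE_PARAM_KEYS = {
    "r", "nu", "mu", "gamma", "beta", "delta", "d", "D",
    "response_kind", "uptake_mask",
}
_CA_PARAM_KEYS = {
    "L", "p0", "q0", "A", "C", "beta", "gamma_deg", "D",
    "relax_iters", "relax_dt", "action_semantics", "baseline_death",
}


def parse_config(doc: dict, source: str = "<config>") -> RunConfig:
    """Validate a parsed configuration mapping and fill documented defaults."""
    doc = _require_mapping(doc, "config")
    _check_unknown(
        doc, {"model", "n_species", "network", "params", "grid", "init", "run",
              "output", "seed"}, "",
    )
    model = doc.pop("model", None)
    if model not in ("pde", "ca"):
        raise ConfigError("`model` must be 'pde' or 'ca'")
    n_hint = doc.pop("n_species", None)
    net = _build_network(doc.pop("network", None), n_hint)
    if n_hint is not None and int(n_hint) != net.n_species:
        raise ConfigError(
            f"`n_species`={n_hint} disagrees with the network ({net.n_species})"
        )
    n = net.n_species

    pblock = _require_mapping(doc.pop("params", None), "params")
    iblock = _require_mapping(doc.pop("init", None), "init")
    rblock = _require_mapping(doc.pop("run", None), "run")
    output = doc.pop("output", "runs")
    seed = doc.pop("seed", None)
    if seed is not None and not isinstance(seed, int):
        raise ConfigError("`seed` must be an integer")

    if model == "pde":
        _check_unknown(pblock, _PDE_PARAM_KEYS, "params.")
        gblock = _require_mapping(doc.pop("grid", None), "grid")
        _check_unknown(gblock, {"nx", "ny", "dx", "boundary"}, "grid.")
        try:
            grid = GridSpec(
                nx=int(gblock.get("nx", 128)),
                ny=int(gblock.get("ny", 128)),
                dx=float(gblock.get("dx", 1.0)),
                boundary=gblock.get("boundary", "dirichlet_zero"),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid `grid`: {exc}") from exc
        try:
            params = ContinuousParameters(
                n_species=n,
                r=pblock.get("r", 0.3),
                nu=pblock.get("nu", 0.5),
                mu=float(pblock.get("mu", 0.4)),
                gamma=float(pblock.get("gamma", 0.1)),
                beta=pblock.get("beta", 0.5),
                delta=pblock.get("delta", 0.1),
                d=pblock.get("d", 0.005),
                D=pblock.get("D", 0.005),
                response_kind=int(pblock.get("response_kind", 2)),
                uptake_mask=pblock.get("uptake_mask", "printed"),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid `params`: {exc}") from exc
        _check_unknown(iblock, {"mode", "radius", "density0", "a", "seed"}, "init.")
        init = {
            "mode": iblock.get("mode", "patches"),
            "radius": iblock.get("radius"),
            "density0": float(iblock.get("density0", 0.25)),
            "a": iblock.get("a"),
            "seed": iblock.get("seed"),
        }
        if init["mode"] not in ("patches", "patchwork"):
            raise ConfigError("`init.mode` must be 'patches' or 'patchwork'")
        _check_unknown(rblock, {"t_end", "dt", "record_dt"}, "run.")
        run = {
            "t_end": float(rblock.get("t_end", 100.0)),
            "dt": float(rblock.get("dt", 0.05)),
            "record_dt": float(rblock.get("record_dt", 1.0)),
        }
        if run["t_end"] <= 0 or run["dt"] <= 0 or run["record_dt"] <= 0:
            raise ConfigError("`run` times must be positive")
    else:
        if "grid" in doc:
            raise ConfigError("unknown key `grid` for model 'ca'")
        grid = None
        _check_unknown(pblock, _CA_PARAM_KEYS, "params.")
        p0 = pblock.get("p0", 0.5)
        if np.any(np.asarray(p0, dtype=float) > 1) or np.any(
            np.asarray(p0, dtype=float) < 0
        ):
            raise ConfigError("`params.p0` must lie in [0, 1]")
        q0 = pblock.get("q0", 0.5)
        if np.any(np.asarray(q0, dtype=float) > 1) or np.any(
            np.asarray(q0, dtype=float) < 0
        ):
            raise ConfigError("`params.q0` must lie in [0, 1]")
        try:
            params = CAParameters(
                n_species=n,
                L=int(pblock.get("L", 100)),
                p0=p0,
                q0=q0,
                A=pblock.get("A", 0.5),
                C=pblock.get("C", 0.5),
                beta=pblock.get("beta", 0.7),
                gamma_deg=pblock.get("gamma_deg", 0.2),
                D=pblock.get("D", 0.001),
                relax_iters=int(pblock.get("relax_iters", 400)),
                relax_dt=pblock.get("relax_dt"),
                action_semantics=pblock.get("action_semantics", "choose"),
                baseline_death=float(pblock.get("baseline_death", 0.0)),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid `params`: {exc}") from exc
        _check_unknown(
            iblock, {"mode", "fill_fraction", "patch_side", "seed"}, "init."
        )
        init = {
            "mode": iblock.get("mode", "patched"),
            "fill_fraction": float(iblock.get("fill_fraction", 0.5)),
            "patch_side": iblock.get("patch_side"),
            "seed": iblock.get("seed"),
        }
        if init["mode"] not in ("patched", "random"):
            raise ConfigError("`init.mode` must be 'patched' or 'random'")
        _check_unknown(rblock, {"n_mcs", "record_every", "seed"}, "run.")
        run = {
            "n_mcs": int(rblock.get("n_mcs", 100)),
            "record_every": int(rblock.get("record_every", 1)),
            "seed": rblock.get("seed"),
        }
        if run["n_mcs"] < 1 or run["record_every"] < 1:
            raise ConfigError("`run.n_mcs` and `run.record_every` must be >= 1")

    return RunConfig(
        model=model,
        network=net,
        params=params,
        grid=grid,
        init=init,
        run=run,
        output=str(output),
        seed=seed,
        raw={"source": source},
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    cfg = parse_config(doc, source=str(path))
    return cfg


# ---------------------------------------------------------------------------
# Snapshot container


def save_state(path, state, extra_attrs: dict | None = None) -> None:
    """Write a snapshot.

    ``state`` is a :class:`FieldState` or a ``(Lattice, ToxinFields)`` pair.
    The layout is one HDF5 group per species with the relevant arrays, plus
    root attributes identifying the model and time stamp.
    """
    with h5py.File(path, "w") as fh:
        if isinstance(state, FieldState):
            fh.attrs["model"] = "pde"
            fh.attrs["t"] = state.t
            g = state.grid
            fh.attrs["nx"], fh.attrs["ny"] = g.nx, g.ny
            fh.attrs["dx"], fh.attrs["boundary"] = g.dx, g.boundary
            for k in range(state.n_species):
                grp = fh.create_group(f"species_{k}")
                grp.create_dataset("N", data=state.N[k])
                grp.create_dataset("B", data=state.B[k])
        else:
            lat, fields = state
            if not isinstance(lat, Lattice) or not isinstance(fields, ToxinFields):
                raise TypeError(
                    "expected FieldState or (Lattice, ToxinFields) pair"
                )
            fh.attrs["model"] = "ca"
            fh.attrs["mcs"] = lat.mcs
            fh.create_dataset("occ", data=lat.occ)
            for k in range(fields.B.shape[0]):
                grp = fh.create_group(f"species_{k}")
                grp.create_dataset("B", data=fields.B[k])
        for key, val in (extra_attrs or {}).items():
            fh.attrs[key] = val


def load_state(path, expect: str | None = None):
    """Read a snapshot back; bit-exact round trip.

    Returns a :class:`FieldState` or a ``(Lattice, ToxinFields)`` pair.
    ``expect`` ('pde' or 'ca') raises a model-mismatch error when the file
    holds the other model's state.
    """
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot read snapshot {path}: {exc}") from exc
    with fh:
        model = fh.attrs.get("model")
        if model not in ("pde", "ca"):
            raise ValueError(f"{path} is not an allelloscape snapshot")
        if expect is not None and model != expect:
            raise ValueError(
                f"model mismatch: {path} holds a '{model}' state, expected "
                f"'{expect}'"
            )
        groups = sorted(
            (k for k in fh if k.startswith("species_")),
            key=lambda s: int(s.split("_")[1]),
        )
        if model == "pde":
            grid = GridSpec(
                nx=int(fh.attrs["nx"]),
                ny=int(fh.attrs["ny"]),
                dx=float(fh.attrs["dx"]),
                boundary=str(fh.attrs["boundary"]),
            )
            N = np.stack([fh[g]["N"][...] for g in groups])
            B = np.stack([fh[g]["B"][...] for g in groups])
            return FieldState(N, B, float(fh.attrs["t"]), grid)
        occ = fh["occ"][...]
        B = np.stack([fh[g]["B"][...] for g in groups])
        return Lattice(occ, int(fh.attrs["mcs"])), ToxinFields(B)


def write_manifest(outdir, cfg: RunConfig, seed, config_doc: dict) -> Path:
    """Write a JSON manifest with everything needed to re-execute the run."""
    import allelloscape

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model": cfg.model,
        "seed": seed,
        "config": config_doc,
        "versions": {
            "allelloscape": allelloscape.__version__,
            "numpy": np.__version__,
            "h5py": h5py.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
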