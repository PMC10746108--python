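"""Run configuration, validation, provenance and result writers.

A run is fully described by a TOML document with (all optional) tables
``[beam]``, ``[solution]``, ``[track]``, ``[engine]``, ``[experiment]`` and
``[scheme]``; defaults give the standard aerated Fricke dosimeter under
500 MeV/u carbon ions.  The resolved configuration is hashed (sha256) and
embedded in every output file so that any number can be traced back to the
exact inputs and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .network import ReactionNetwork, load_scheme
from .solution import BulkSolution
from .track import BeamSpec, TrackModelParams


class ConfigError(ValueError):
    """Configuration failure, reported with the offending field path."""


@dataclass
class RunConfig:
    """Validated, fully-resolved run description."""

    beam: BeamSpec
    solution: BulkSolution
    network: ReactionNetwork
    track_params: TrackModelParams
    t_handoff: float = 1.0e-6
    cutoff_max_nm: float = 120.0
    experiment: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "results"

    def resolved_dict(self) -> dict:
        return {
            "beam": {
                "ion": self.beam.ion,
                "energy_per_nucleon": self.beam.energy_per_nucleon,
                "let_value": self.beam.let_value,
                "segment_length": self.beam.segment_length,
            },
            "solution": {
                "concentrations": dict(self.solution.concentrations),
                "ionic_strength": self.solution.ionic_strength,
            },
            "track": self.track_params.as_dict(),
            "engine": {
                "t_handoff": self.t_handoff,
                "cutoff_max_nm": self.cutoff_max_nm,
            },
            "experiment": dict(self.experiment),
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.resolved_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _get(table: dict, key: str, default, path: str, kind=None):
    val = table.get(key, default)
    if kind is not None and val is not None and not isinstance(val, kind):
        try:
            val = kind(val)
        except (TypeError, ValueError):
            raise ConfigError(f"{path}.{key}: expected {kind.__name__}, got {val!r}")
    return val


def load_and_validate_config(source) -> RunConfig:
    """Parse and validate a TOML run configuration.

    ``source`` is a path, a TOML string, or a dict.  Schema violations are
    reported with their field path; a minimal/empty document resolves to the
    standard Fricke composition under 500 MeV/u carbon ions.
    """
    if isinstance(source, dict):
        doc = source
    else:
        p = Path(str(source))
        try:
            text = p.read_text() if p.is_file() else str(source)
        except OSError:
            text = str(source)
        try:
            doc = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"config does not parse as TOML: {exc}") from exc

    beam_t = doc.get("beam", {})
    energy = _get(beam_t, "energy_per_nucleon", None, "beam", float)
    let = _get(beam_t, "let_value", None, "beam", float)
    if energy is None and let is None:
        energy = 500.0
    try:
        beam = BeamSpec(
            ion=_get(beam_t, "ion", "12C6+", "beam", str),
            energy_per_nucleon=energy,
            let_value=let,
            segment_length=_get(beam_t, "segment_length", None, "beam", float),
        )
    except ValueError as exc:
        raise ConfigError(f"beam: {exc}") from exc

    sol_t = doc.get("solution", {})
    cystamine = _get(sol_t, "cystamine", 0.0, "solution", float)
    if cystamine < 0:
        raise ConfigError("solution.cystamine: must be >= 0")
    try:
        solution = BulkSolution.fricke(
            cystamine,
            fe2=_get(sol_t, "fe2", 1.0e-3, "solution", float),
            o2=_get(sol_t, "o2", 2.5e-4, "solution", float),
            h2so4=_get(sol_t, "h2so4", 0.4, "solution", float),
            ionic_strength=_get(sol_t, "ionic_strength", None, "solution", float),
            count_cystamine_in_ionic_strength=_get(
                sol_t, "count_cystamine_in_ionic_strength", False, "solution"
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"solution: {exc}") from exc

    network = load_scheme(doc.get("scheme"))
    for name in solution.concentrations:
        if name not in network.species:
            raise ConfigError(f"solution.concentrations.{name}: unknown species")

    track_t = dict(doc.get("track", {}))
    try:
        track_params = TrackModelParams(**track_t)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"track: {exc}") from exc

    eng_t = doc.get("engine", {})
    t_handoff = _get(eng_t, "t_handoff", 1.0e-6, "engine", float)
    if t_handoff < 1.0e-12:
        raise ConfigError("engine.t_handoff: must be >= 1 ps")

    return RunConfig(
        beam=beam,
        solution=solution,
        network=network,
        track_params=track_params,
        t_handoff=t_handoff,
        cutoff_max_nm=_get(eng_t, "cutoff_max_nm", 120.0, "engine", float),
        experiment=dict(doc.get("experiment", {})),
        seed=int(doc.get("seed", 0)),
        output_dir=str(doc.get("output_dir", "results")),
    )


# ----------------------------------------------------------------- writers


def write_results(outputs: dict, out_dir, *, config: RunConfig | None = None) -> list:
    """Write result tables (CSV) plus a JSON metadata sidecar.

    ``outputs`` maps basenames to pandas DataFrames (written as
    ``<name>.csv``) or JSON-serializable dicts (``<name>.json``).  Metadata
    records the config hash, seeds and package version for bit-identical
    replay of the deterministic stages.
    """
    import pandas as pd

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    meta = {
        "trackchem_version": __version__,
        "config_hash": config.config_hash if config else None,
        "config": config.resolved_dict() if config else None,
    }
    for name, obj in outputs.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        written.append(path)
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    written.append(meta_path)
    return written


def track_to_files(segment, out_dir, *, basename: str = "track") -> list:
    """Serialize a track segment: CSV (species, x, y, z, weight) + JSON
    metadata (beam, LET, energy, parameters) for replay into the engine."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "species": [segment.species_names[c] for c in segment.species],
            "x_nm": segment.positions[:, 0],
            "y_nm": segment.positions[:, 1],
            "z_nm": segment.positions[:, 2],
            "weight": segment.weights,
        }
    )
    csv_path = out / f"{basename}.csv"
    df.to_csv(csv_path, index=False)
    meta = {
        "ion": segment.beam.ion,
        "let_kev_um": segment.let_value,
        "segment_length_nm": segment.segment_length_nm,
        "deposited_energy_ev": segment.deposited_energy,
        "total_energy_ev": segment.total_energy,
        "birth_time_s": segment.birth_time,
        "params": segment.params.as_dict() if segment.params else None,
    }
    meta_path = out / f"{basename}.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return [csv_path, meta_path]
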