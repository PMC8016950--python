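"""End-to-end humanization pipeline with config, provenance and artifacts.

Stages: number the donor and candidate acceptor V regions, rank acceptors by
framework-restricted superposition (on a generated structural library), graft
the donor CDRs onto the best human acceptor, apply the configured
back-mutations, and characterize a reference complex interface.  Each stage
writes a JSON artifact; a provenance record carries the config echo, its
SHA-256 hash and package versions.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .humanize import (BackMutation, apply_back_mutations, diff_frameworks,
                       graft_cdrs, propose_nterminal_backmutations,
                       propose_vernier_backmutations)
from .interface import SasaParams, buried_surface, contact_table, hydrogen_bonds
from .kabat import RegionPartition, kabat_number_sequence, parse_kabat_position
from .refdata import FINAL_BACKMUTATIONS, V_REGION_LIBRARY, V_REGION_SOURCES
from .structures import find_disulfides, peptide_omega_and_cis
from .superpose import filter_by_source, rank_acceptors
from .synth import DecoySpec, make_decoy_library, make_fv_template, make_toy_complex


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, last_artifact: str | None = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.last_artifact = last_artifact


_ALLOWED_KEYS = {
    "donor", "acceptors", "allowed_sources", "chothia_l1", "r0",
    "backmutations", "decoy_sigma", "seed", "outdir",
    "sasa_points", "probe_radius", "bsa_threshold", "hbond_cutoff",
    "cis_cutoff", "ss_cutoff",
}

DEFAULT_CONFIG = {
    "donor": "M3/38",
    "acceptors": ["4NRY", "3KYM", "4KQ3", "5I8C"],
    "allowed_sources": ["Human"],
    "chothia_l1": True,
    "r0": 3.0,
    "backmutations": list(FINAL_BACKMUTATIONS),
    "decoy_sigma": 0.3,
    "seed": 0,
    "outdir": "pipeline_out",
    "sasa_points": 480,
    "probe_radius": 1.4,
    "bsa_threshold": 1.0,
    "hbond_cutoff": 3.5,
    "cis_cutoff": 30.0,
    "ss_cutoff": 2.3,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML file and overrides; validate keys."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must hold a mapping")
        config.update(loaded)
    if overrides:
        config.update(overrides)
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("donor",):
        if config[key] not in V_REGION_LIBRARY:
            raise ConfigError(f"{key} {config[key]!r} not in the built-in library")
    for acc in config["acceptors"]:
        if acc not in V_REGION_LIBRARY:
            raise ConfigError(f"acceptor {acc!r} not in the built-in library")
    if config["r0"] <= 0:
        raise ConfigError("r0 must be positive")
    return config


def config_hash(config: dict) -> str:
    # outdir is a filesystem location, not part of the scientific config
    hashed = {k: v for k, v in config.items() if k != "outdir"}
    blob = json.dumps(hashed, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_artifact(outdir: Path, name: str, payload: dict, chash: str) -> Path:
    payload = dict(payload)
    payload["config_hash"] = chash
    path = outdir / f"{name}.json"
    path.write_text(json.dumps(payload, sort_keys=True, indent=1, default=str))
    return path


def run_humanization_pipeline(config: dict) -> dict:
    """Run number -> search -> graft -> interface -> report.

    Returns a summary dict with the per-stage artifact paths, the ranked
    candidates, the final design and the interface report.  A stage failure
    raises :class:`StageError` naming the stage and the last artifact
    written.
    """
    chash = config_hash(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list = []
    seed = int(config["seed"])
    partition = RegionPartition.default(chothia_l1=bool(config["chothia_l1"]))

    def fail(stage, exc):
        raise StageError(stage, str(exc), str(artifacts[-1]) if artifacts else None) from exc

    # stage 1: numbering
    try:
        numbered = {}
        for name in [config["donor"], *config["acceptors"]]:
            vh, vl = V_REGION_LIBRARY[name]
            numbered[name] = (kabat_number_sequence(vh, "H", name),
                              kabat_number_sequence(vl, "L", name))
        artifacts.append(_write_artifact(outdir, "01_numbering", {
            "domains": {name: {"H": h.to_json_obj(), "L": l.to_json_obj()}
                        for name, (h, l) in numbered.items()}}, chash))
    except Exception as exc:  # noqa: BLE001
        fail("numbering", exc)

    # stage 2: acceptor search on a generated structural library
    try:
        query = make_fv_template(config["donor"], seed=seed)
        library = []
        for i, name in enumerate(config["acceptors"]):
            template = make_fv_template(name, seed=seed + 1 + i)
            decoys, _ = make_decoy_library(
                template, DecoySpec(n_decoys=1, seed=seed + 100 + i),
                sigmas=[config["decoy_sigma"] * (1 + 0.5 * i)])
            fv, _meta = decoys[0]
            library.append((fv, {"pdb_id": name,
                                 "source_tag": V_REGION_SOURCES.get(name, "unknown")}))
        candidates, failures = rank_acceptors(query, library, partition, config["r0"])
        human = filter_by_source(candidates, config["allowed_sources"])
        if not human:
            raise RuntimeError("no acceptor passed the source filter")
        best = human[0]
        artifacts.append(_write_artifact(outdir, "02_acceptor_search", {
            "candidates": [{"pdb_id": c.pdb_id, "q": round(c.q, 4),
                            "rmsd": round(c.rmsd, 4), "n_align": c.n_align,
                            "n_residue": c.n_residue,
                            "seq_identity": round(c.seq_identity),
                            "source_tag": c.source_tag} for c in candidates],
            "failures": failures, "selected": best.pdb_id}, chash))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("acceptor_search", exc)

    # stage 3: grafting and back-mutations
    try:
        donor_pair = numbered[config["donor"]]
        acceptor_pair = numbered[best.pdb_id]
        design = graft_cdrs(donor_pair, acceptor_pair, partition,
                            donor_id=config["donor"], acceptor_id=best.pdb_id)
        proposals = {str(bm.position): bm
                     for bm in propose_vernier_backmutations(donor_pair, acceptor_pair,
                                                             partition=partition)
                     + propose_nterminal_backmutations(donor_pair, acceptor_pair,
                                                       partition=partition)}
        selected = []
        dh, dl = donor_pair[0].as_dict(), donor_pair[1].as_dict()
        ah, al = acceptor_pair[0].as_dict(), acceptor_pair[1].as_dict()
        for label in config["backmutations"]:
            if label in proposals:
                selected.append(proposals[label])
                continue
            pos = parse_kabat_position(label)
            d = dh if pos.chain_kind == "H" else dl
            a = ah if pos.chain_kind == "H" else al
            if pos not in d or pos not in a:
                raise RuntimeError(f"back-mutation position {label} absent from sequences")
            if d[pos] == a[pos]:
                continue  # nothing to restore
            selected.append(BackMutation(pos, d[pos], a[pos], "refinement",
                                         "configured refinement position"))
        design = apply_back_mutations(design, selected)
        diff = diff_frameworks((design.heavy, design.light), acceptor_pair, partition)
        artifacts.append(_write_artifact(outdir, "03_graft", {
            "design": design.to_json_obj(),
            "framework_diff_vs_acceptor": [[str(p), a, b] for p, a, b in diff["framework"]],
        }, chash))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("graft", exc)

    # stage 4: interface characterization of the bundled reference complex
    try:
        toy = make_toy_complex(seed=seed)
        model = toy["model"]
        params = SasaParams(probe_radius=float(config["probe_radius"]),
                            points_per_atom=int(config["sasa_points"]))
        report = buried_surface(model, ["H", "L"], ["P"], params)
        hb = hydrogen_bonds(model, ["H", "L"], ["P"], float(config["hbond_cutoff"]))
        table = contact_table(report, float(config["bsa_threshold"]), hb)
        geometry = peptide_omega_and_cis(model, float(config["cis_cutoff"]))
        bridges = find_disulfides(model, float(config["ss_cutoff"]))
        artifacts.append(_write_artifact(outdir, "04_interface", {
            "peptide_sasa_free": round(report.total_sasa_b_free, 2),
            "peptide_buried": round(report.buried_b, 2),
            "buried_fraction_pct": round(report.buried_fraction, 2),
            "contacts": [{"residue": r.label, "bsa": round(r.bsa, 2),
                          "hbond": r.hbond, "polarity": r.polarity} for r in table],
            "n_direct_hbonds": len(hb["direct"]),
            "n_water_mediated": len(hb["water_mediated"]),
            "n_cis_bonds": len(geometry.cis_bonds),
            "n_disulfides": len(bridges)}, chash))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("interface", exc)

    # stage 5: provenance + summary
    provenance = {
        "config": config, "config_hash": chash,
        "graftkit_version": __version__,
        "stages": [p.name for p in artifacts],
    }
    artifacts.append(_write_artifact(outdir, "05_provenance", provenance, chash))
    return {
        "artifacts": [str(p) for p in artifacts],
        "selected_acceptor": best.pdb_id,
        "n_back_mutations": len(design.back_mutations),
        "config_hash": chash,
    }
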