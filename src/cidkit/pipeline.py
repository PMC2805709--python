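"""End-to-end orchestration: profiles → motifs → contacts → tree.

A :class:`RunConfig` names the inputs and thresholds; :func:`run_pipeline`
executes the requested stages in order, writes TSV/Newick outputs with
floats at 6 significant digits (stable diffs), and records a JSON
manifest with the config hash, input checksums and per-stage summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import cidkit
from cidkit import alignment as aln_io
from cidkit import contacts as contacts_mod
from cidkit import motifs as motifs_mod
from cidkit import phylogeny as phylo_mod
from cidkit import profiles as profiles_mod

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_STAGE_ERROR = 3


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, toggles and thresholds for a pipeline run."""

    alignment_path: Optional[str] = None
    structure_paths: Sequence[str] = ()
    out_dir: str = "cidkit_out"
    seed: int = 0
    run_profiles: bool = True
    run_motifs: bool = True
    run_contacts: bool = True
    run_tree: bool = True
    profile: profiles_mod.ProfileConfig = field(
        default_factory=profiles_mod.ProfileConfig
    )
    motif_min_occupancy: float = motifs_mod.DEFAULT_MIN_OCCUPANCY
    motif_definitions_path: Optional[str] = None
    criteria: contacts_mod.ContactCriteria = field(
        default_factory=contacts_mod.ContactCriteria
    )
    ligand_residues: Sequence[str] = tuple(sorted(contacts_mod.SUGAR_CODES))
    subsites: Optional[Sequence[int]] = None
    tree_correction: str = "none"
    map_ambiguous_to_gap: bool = False

    def validate(self) -> None:
        if (self.run_profiles or self.run_motifs or self.run_tree) and (
            self.alignment_path is None
        ):
            raise ConfigError("alignment_path required for sequence stages")
        if self.alignment_path and not Path(self.alignment_path).exists():
            raise ConfigError(f"alignment not found: {self.alignment_path}")
        for p in self.structure_paths:
            if not Path(p).exists():
                raise ConfigError(f"structure not found: {p}")
        if self.run_contacts and not self.structure_paths:
            raise ConfigError("structure_paths required for the contact stage")
        if self.tree_correction not in ("none", "kimura"):
            raise ConfigError(f"unknown correction {self.tree_correction!r}")
        if not 0.0 <= self.motif_min_occupancy <= 1.0:
            raise ConfigError("motif_min_occupancy must lie in [0, 1]")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["profile"]["scale"] = self.profile.scale.name
        d["structure_paths"] = list(self.structure_paths)
        d["ligand_residues"] = list(self.ligand_residues)
        d["subsites"] = None if self.subsites is None else list(self.subsites)
        return d


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fmt_frame(df) -> str:
    return df.to_csv(sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest.

    Any stage exception is re-raised as :class:`StageError` naming the
    stage, after logging; nothing further runs.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": cidkit.__version__,
        "config": cfg.to_jsonable(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
        "skipped": [],
    }
    if cfg.alignment_path:
        manifest["inputs"][cfg.alignment_path] = _sha256(cfg.alignment_path)
    for p in cfg.structure_paths:
        manifest["inputs"][p] = _sha256(p)

    aln = None
    profile_result = None
    if cfg.alignment_path:
        aln = aln_io.read_alignment(
            cfg.alignment_path, map_ambiguous_to_gap=cfg.map_ambiguous_to_gap
        )

    if cfg.run_profiles:
        try:
            profile_result = profiles_mod.profile_alignment(aln, cfg.profile)
            (out / "profile.tsv").write_text(
                _fmt_frame(profile_result.to_frame())
            )
            bins = [c.bin for c in profile_result.conservation]
            manifest["stages"]["profiles"] = {
                "columns": aln.L,
                "n_high": bins.count("high"),
                "n_moderate": bins.count("moderate"),
                "n_low": bins.count("low"),
                "n_gap_zeroed": bins.count("gap_zeroed"),
                "histogram": profile_result.histogram,
            }
        except Exception as exc:
            logger.error("profiles stage failed: %s", exc)
            raise StageError("profiles", exc) from exc
    else:
        manifest["skipped"].append("profiles")

    if cfg.run_motifs:
        try:
            if profile_result is None:
                profile_result = profiles_mod.profile_alignment(
                    aln, cfg.profile
                )
            if cfg.motif_definitions_path:
                defs = motifs_mod.load_motif_definitions(
                    cfg.motif_definitions_path
                )
            else:
                defs = motifs_mod.default_motifs(cfg.motif_min_occupancy)
            hits = motifs_mod.scan_motifs(
                aln, profile_result.conservation, defs
            )
            (out / "motifs.tsv").write_text(motifs_mod.hits_to_tsv(hits))
            manifest["stages"]["motifs"] = {
                "n_hits": len(hits),
                "anchors": {
                    h.motif_id: h.anchor_column for h in hits
                },
            }
        except Exception as exc:
            logger.error("motifs stage failed: %s", exc)
            raise StageError("motifs", exc) from exc
    else:
        manifest["skipped"].append("motifs")

    if cfg.run_contacts:
        try:
            summary = {}
            for path in cfg.structure_paths:
                model = contacts_mod.parse_structure(path)
                ligand = contacts_mod.select_ligand(
                    model, set(cfg.ligand_residues), subsites=cfg.subsites
                )
                recs = (
                    contacts_mod.find_hbonds(model, ligand, cfg.criteria)
                    + contacts_mod.find_water_mediated_hbonds(
                        model, ligand, cfg.criteria
                    )
                    + contacts_mod.find_hydrophobic_contacts(
                        model, ligand, cfg.criteria
                    )
                    + contacts_mod.find_salt_bridges(model, cfg.criteria)
                    + contacts_mod.find_pi_cation(model, cfg.criteria)
                )
                stem = Path(path).stem
                (out / f"contacts_{stem}.tsv").write_text(
                    contacts_mod.contacts_to_tsv(recs)
                )
                by_kind: dict[str, int] = {}
                for r in recs:
                    by_kind[r.kind] = by_kind.get(r.kind, 0) + 1
                summary[stem] = by_kind
            manifest["stages"]["contacts"] = summary
        except Exception as exc:
            logger.error("contacts stage failed: %s", exc)
            raise StageError("contacts", exc) from exc
    else:
        manifest["skipped"].append("contacts")

    if cfg.run_tree:
        try:
            dm = phylo_mod.distance_matrix(aln, cfg.tree_correction)
            (out / "distances.tsv").write_text(
                phylo_mod.distance_matrix_to_tsv(dm)
            )
            tree = phylo_mod.nj_tree(dm)
            phylo_mod.write_newick(tree, out / "tree.nwk")
            manifest["stages"]["tree"] = {
                "n_leaves": tree.count(tips=True),
                "clamped_branches": bool(getattr(tree, "clamped", False)),
            }
        except Exception as exc:
            logger.error("tree stage failed: %s", exc)
            raise StageError("tree", exc) from exc
    else:
        manifest["skipped"].append("tree")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
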