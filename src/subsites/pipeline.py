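"""End-to-end orchestration: annotate -> model -> sample -> observe ->
entropy -> compare, with a discard manifest naming the filter that removed
each structure and deterministic, seed-reproducible outputs.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import (
    CatalyticAnnotation,
    PocketAssignment,
    assign_pockets_from_reference,
    catalytic_site_occupancy,
    close_annotation_gaps,
    detect_peptide_ligands,
    filter_assignment,
    project_annotation,
    strip_capping_groups,
)
from .constants import POCKET_ORDER, POSITION_ORDER
from .entropy import cleavage_entropy, load_specificity_matrix, spearman_per_position
from .errors import SubsitesError, UnmodellableComplex
from .modelling import generate_library, reconstruct_missing, thread_library
from .observables import (
    OBSERVABLE_NAMES,
    average_observables,
    frame_observables,
    shrake_rupley_asa,
)
from .sampling import EnergyModel, SamplerConfig, run_sampling
from .structure import Structure, parse_pdb


@dataclass
class PipelineConfig:
    pocket_cutoff: float = 4.5
    projection_cutoff: float = 2.0
    identity_floor: float = 0.5
    min_ligand_len: int = 3
    max_ligand_len: int = 12
    min_assigned: int = 3
    occupancy_threshold: float = 0.0
    library_n: int = 480
    library_seed: int = 0
    n_steps: int = 5000
    kT: float = 1.2
    frame_stride: int = 10
    sampler_seed: int = 0
    asa_points: int = 240
    stages: str = "annotate,model,sample,observe,entropy,compare"

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        values: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = (x.strip() for x in line.split("=", 1))
                values[k] = v
        kwargs = {}
        for f_name, f_type in cls.__annotations__.items():
            if f_name not in values:
                continue
            raw = values[f_name]
            if f_type == "float":
                kwargs[f_name] = float(raw)
            elif f_type == "int":
                kwargs[f_name] = int(raw)
            else:
                kwargs[f_name] = raw
        return cls(**kwargs)


def read_catalytic_table(path: str, source_id: Optional[str] = None) -> CatalyticAnnotation:
    df = pd.read_csv(path, sep="\t")
    if source_id is not None and "pdb_id" in df.columns:
        sel = df[df.pdb_id == source_id]
        if len(sel):
            df = sel
    return CatalyticAnnotation(
        [(str(r.chain), int(r.res_seq), str(r.role)) for r in df.itertuples()]
    )


def read_reference_positions(path: str) -> list[tuple[tuple[str, int, str], str]]:
    df = pd.read_csv(path, sep="\t")
    return [((str(r.chain), int(r.res_seq), ""), str(r.pocket)) for r in df.itertuples()]


@dataclass
class PipelineResult:
    out_dir: str
    kept: list[str] = field(default_factory=list)
    discards: list[tuple[str, str, str]] = field(default_factory=list)  # id, stage, reason
    summary: Optional[pd.DataFrame] = None
    correlations: Optional[pd.DataFrame] = None

    @property
    def exit_code(self) -> int:
        if not self.kept:
            return 2
        return 1 if self.discards else 0


def _target_sequence(structure: Structure, assignment: PocketAssignment) -> str:
    by_pocket = {}
    for key, label in assignment.peptide_map:
        if label is not None:
            by_pocket[label] = structure.residue(key).one_letter
    return "".join(by_pocket.get(p, "A") if by_pocket.get(p, "A") != "X" else "A"
                   for p in POCKET_ORDER)


def _annotate_one(
    structure: Structure,
    catalytic: CatalyticAnnotation,
    config: PipelineConfig,
    ref_positions=None,
    ref_structure: Optional[Structure] = None,
    ref_assignment: Optional[PocketAssignment] = None,
):
    ligands = detect_peptide_ligands(
        structure, min_len=config.min_ligand_len, max_len=config.max_ligand_len
    )
    if not ligands:
        raise SubsitesError("no peptide-like ligand of 3-12 residues")
    ligand = strip_capping_groups(ligands[0])
    if ligand.length < config.min_ligand_len:
        raise SubsitesError("peptide shorter than 3 residues after cap removal")
    asa_engine = lambda s: shrake_rupley_asa(s, n_sphere_points=config.asa_points)  # noqa: E731
    if not catalytic_site_occupancy(
        structure, catalytic, ligand, asa_engine, config.occupancy_threshold
    ):
        raise SubsitesError("ligand does not occupy the catalytic site (dASA = 0)")
    if ref_structure is not None and ref_assignment is not None:
        assignment = project_annotation(
            ref_structure,
            ref_assignment,
            structure,
            proj_cutoff=config.projection_cutoff,
            pocket_cutoff=config.pocket_cutoff,
        )
    else:
        if ref_positions is None:
            raise SubsitesError("no reference positions or reference complex given")
        keys = {k for k, _ in ref_positions}
        positions = [
            (k, lab) for k, lab in ref_positions if structure.residue(k) is not None
        ]
        if len(positions) < len(keys):
            raise SubsitesError("reference positions missing from structure")
        assignment = assign_pockets_from_reference(
            structure, positions, cutoff=config.pocket_cutoff
        )
    assignment = close_annotation_gaps(assignment)
    decision = filter_assignment(assignment, config.min_assigned)
    if not decision.keep:
        raise SubsitesError(decision.reason)
    return ligand, assignment


def run_pipeline(
    config: PipelineConfig,
    structure_paths: list[str],
    catalytic_path: str,
    out_dir: str,
    ref_positions_path: Optional[str] = None,
    matrix_path: Optional[str] = None,
    ref_structure_path: Optional[str] = None,
) -> PipelineResult:
    """Run the full workflow and write per-stage outputs under ``out_dir``.

    Every input structure lands exactly once in either the kept outputs or
    the discard manifest with the reason that removed it.
    """
    os.makedirs(out_dir, exist_ok=True)
    config.to_file(os.path.join(out_dir, "config.txt"))
    result = PipelineResult(out_dir)
    log_lines: list[str] = [f"seed library={config.library_seed} sampler={config.sampler_seed}"]

    ref_positions = (
        read_reference_positions(ref_positions_path) if ref_positions_path else None
    )
    ref_structure = ref_assignment = None
    if ref_structure_path is not None and ref_positions is not None:
        with open(ref_structure_path) as fh:
            ref_structure = parse_pdb(fh.read(), os.path.basename(ref_structure_path))
        ref_assignment = assign_pockets_from_reference(
            ref_structure, ref_positions, cutoff=config.pocket_cutoff
        )

    all_records = []
    annotation_rows = []
    per_structure_profiles: dict[str, dict[str, np.ndarray]] = {}
    model = EnergyModel()
    for path in structure_paths:
        source_id = os.path.splitext(os.path.basename(path))[0]
        try:
            with open(path) as fh:
                structure = parse_pdb(fh.read(), source_id)
            catalytic = read_catalytic_table(catalytic_path, source_id=None)
            ligand, assignment = _annotate_one(
                structure, catalytic, config,
                ref_positions=ref_positions,
                ref_structure=ref_structure,
                ref_assignment=ref_assignment,
            )
            annotation_rows.append(
                {
                    "pdb_id": source_id,
                    "peptide_aa": ligand.sequence,
                    "pockets": "-".join(
                        lab or "." for _, lab in assignment.peptide_map
                    ),
                    "res_seq": "-".join(
                        str(k[1]) for k, _ in assignment.peptide_map
                    ),
                    "chain": assignment.peptide_chain_id,
                }
            )
            log_lines.append(f"{source_id}: annotated {assignment.assigned_count} positions")

            # model: extend to a full 8-mer, thread the random library
            target = _target_sequence(structure, assignment)
            try:
                modelled = reconstruct_missing(structure, assignment, target)
            except UnmodellableComplex as exc:
                raise SubsitesError(f"unmodellable: {exc}") from exc
            pep_chain = modelled.chain(assignment.peptide_chain_id)
            full_map = [
                (r.key(pep_chain.chain_id), POCKET_ORDER[i])
                for i, r in enumerate(pep_chain.residues)
            ]
            full_assign = assign_pockets_from_reference(
                modelled, full_map, cutoff=config.pocket_cutoff
            )
            library = generate_library(
                n=config.library_n, seed=config.library_seed,
                library_id=f"{source_id}-lib",
            )
            with open(os.path.join(out_dir, f"{source_id}_library.txt"), "w") as fh:
                fh.write(library.to_text())
            threaded = thread_library(modelled, library, pep_chain.chain_id)
            log_lines.append(f"{source_id}: threaded {len(threaded)} complexes")

            # sample + observe
            records = []
            for run_index, complex_ in enumerate(threaded):
                cfg = SamplerConfig(
                    n_steps=config.n_steps,
                    kT=config.kT,
                    frame_stride=config.frame_stride,
                    seed=config.sampler_seed + run_index,
                )
                traj = run_sampling(
                    complex_, cfg, model, assignment=full_assign, run_index=run_index
                )
                for f, frame in enumerate(traj.frames):
                    records.append(
                        frame_observables(
                            frame, full_assign, model,
                            run_index=run_index, frame_index=f,
                            n_sphere_points=config.asa_points,
                        )
                    )
            table = average_observables(records)
            all_records.extend(records)
            profiles = {
                obs: table.per_position(obs).to_numpy() for obs in OBSERVABLE_NAMES
            }
            per_structure_profiles[source_id] = profiles
            result.kept.append(source_id)
        except SubsitesError as exc:
            result.discards.append((source_id, "pipeline", str(exc)))
            log_lines.append(f"{source_id}: DISCARDED ({exc})")

    # manifest and annotation table
    with open(os.path.join(out_dir, "discards.tsv"), "w") as fh:
        fh.write("pdb_id\tstage\treason\n")
        for sid, stage, reason in result.discards:
            fh.write(f"{sid}\t{stage}\t{reason}\n")
    pd.DataFrame(
        annotation_rows,
        columns=["pdb_id", "peptide_aa", "pockets", "res_seq", "chain"],
    ).to_csv(os.path.join(out_dir, "annotation.tsv"), sep="\t", index=False)

    if all_records:
        table = average_observables(all_records)
        table.table.to_csv(
            os.path.join(out_dir, "observables.tsv"), sep="\t", index=False,
            float_format="%.6f",
        )
        rows = []
        for obs in OBSERVABLE_NAMES:
            raw = table.per_position(obs)
            norm = table.per_position(obs, normalized=True)
            for pos in raw.index:
                rows.append(
                    {"observable": obs, "position": pos,
                     "mean": raw[pos], "normalized": norm[pos]}
                )
        result.summary = pd.DataFrame(rows)
        result.summary.to_csv(
            os.path.join(out_dir, "summary.tsv"), sep="\t", index=False,
            float_format="%.6f",
        )

    if matrix_path is not None and result.kept:
        with open(matrix_path) as fh:
            matrix = load_specificity_matrix(fh.read())
        profile = cleavage_entropy(matrix)
        ent = pd.DataFrame(
            {"position": list(POSITION_ORDER),
             "H": [profile.H[p] for p in POSITION_ORDER]}
        )
        ent.to_csv(os.path.join(out_dir, "entropy.tsv"), sep="\t", index=False,
                   float_format="%.6f")
        rows = []
        for obs in OBSERVABLE_NAMES:
            obs_profiles = [per_structure_profiles[s][obs] for s in result.kept]
            ent_profiles = [profile.vector() for _ in result.kept]
            try:
                rho = spearman_per_position(obs_profiles, ent_profiles)
            except SubsitesError:
                continue
            rows.append({"observable": obs, "spearman": rho})
        result.correlations = pd.DataFrame(rows)
        result.correlations.to_csv(
            os.path.join(out_dir, "correlations.tsv"), sep="\t", index=False,
            float_format="%.6f",
        )

    with open(os.path.join(out_dir, "log.txt"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return result
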