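"""End-to-end orchestration of the analysis stages from one declarative
configuration.

A :class:`PipelineConfig` names the inputs, toggles stages and carries
per-stage parameters (distance saturation ceiling, bootstrap replicates,
divergence cut-offs, ANM cutoff, PCA occupancy) plus one seed.  Stages
run in dependency order; every emitted file is listed in a manifest with
the stage, parameters, seed and an input/content hash so that a rerun
with the same configuration reproduces identical tables.

The ``demo`` entry point builds a fully synthetic end-to-end run — the
generators supply the family alignment, codon alignment and structural
ensemble, and every analysis stage consumes them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    anm_modes,
    bootstrap_support,
    build_hessian,
    candidate_sites_type1,
    ensemble_pca,
    estimate_type1,
    estimate_type2,
    find_pest,
    fitch_counts,
    group_range_matrix,
    iterative_superposition,
    jc_distance,
    make_ankyrin_calpha,
    make_ensemble,
    mean_square_fluctuation,
    mode_overlap,
    nj_tree,
    read_alignment,
    read_fasta,
    read_newick,
    read_pdb_calpha,
    simulate_codons,
    simulate_family,
    sitewise_kaks,
    two_clade_tree,
    write_newick,
)
from .functional_divergence import ClusterPair
from .io_formats import write_fasta, write_pdb_calpha

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

logger = logging.getLogger("ankevo.pipeline")

STAGES = ("similarity", "pest", "phylogeny", "divergence", "kaks", "anm", "pca")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs (filled in by the demo generator or by the user)
    msa_path: str | None = None
    codon_msa_path: str | None = None
    pdb_paths: list[str] = field(default_factory=list)
    tree_path: str | None = None
    groups: dict[str, str] = field(default_factory=dict)  # taxon -> group
    cluster_a: list[str] = field(default_factory=list)
    cluster_b: list[str] = field(default_factory=list)
    kaks_query: str | None = None
    outgroup: str | None = None
    # stage parameters (pipeline-wide defaults)
    bootstrap_replicates: int = 100
    anm_cutoff: float = 15.0
    type1_cutoff: float = 0.85
    type2_cutoff: float = 17.0
    identity_min: float = 35.0
    min_occupancy: float = 0.9
    pest_threshold: float = 5.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        needed = []
        if {"similarity", "pest", "phylogeny", "divergence"} & set(self.stages):
            needed.append(self.msa_path)
        if "kaks" in self.stages:
            needed.append(self.codon_msa_path)
        for p in needed:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")
        if "anm" in self.stages or "pca" in self.stages:
            for p in self.pdb_paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing PDB input: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a manifest: one entry per stage with the parameters used and
    the output files written (each with a content hash).  A stage
    failure halts the run; the partial manifest is preserved inside the
    raised exception's ``manifest`` attribute.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "parameters": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }
        logger.info("stage %s: wrote %s", stage, [f.name for f in files])

    try:
        msa = read_alignment(config.msa_path) if config.msa_path else None
        tree = read_newick(config.tree_path) if config.tree_path else None

        if "similarity" in config.stages:
            ungapped = {
                s.id: dataclasses.replace(s, residues=s.ungapped)
                for s in msa.sequences
            }
            groups: dict[str, list] = {}
            for taxon, grp in config.groups.items():
                groups.setdefault(grp, []).append(ungapped[taxon])
            if len(groups) >= 2:
                table = group_range_matrix(groups, metric="similarity")
                f = out / "similarity_ranges.tsv"
                table.to_table().to_csv(f, sep="\t")
                record("similarity", {"metric": "similarity"}, [f])

        if "pest" in config.stages:
            rows = []
            for s in msa.sequences:
                seq = dataclasses.replace(s, residues=s.ungapped)
                for region in find_pest(seq, threshold=config.pest_threshold):
                    rows.append(
                        {
                            "sequence": s.id,
                            "start": region.start,
                            "end": region.end,
                            "score": round(region.score, 2),
                            "valid": region.valid,
                        }
                    )
            f = out / "pest_regions.tsv"
            pd.DataFrame(
                rows, columns=["sequence", "start", "end", "score", "valid"]
            ).to_csv(f, sep="\t", index=False)
            record("pest", {"threshold": config.pest_threshold}, [f])

        if "phylogeny" in config.stages:
            boot = bootstrap_support(
                msa, replicates=config.bootstrap_replicates, seed=config.seed
            )
            if config.outgroup:
                from .phylogeny import root_with_outgroup

                boot = root_with_outgroup(boot, config.outgroup)
            f = out / "nj_bootstrap.nwk"
            write_newick(boot, f)
            tree = tree or boot
            record(
                "phylogeny",
                {"replicates": config.bootstrap_replicates, "seed": config.seed},
                [f],
            )

        if "divergence" in config.stages:
            pair = ClusterPair(
                msa,
                tree,
                frozenset(config.cluster_a),
                frozenset(config.cluster_b),
            )
            counts = fitch_counts(pair)
            t1 = estimate_type1(counts, pair, seed=config.seed)
            sites1 = candidate_sites_type1(t1, cutoff=config.type1_cutoff)
            t2 = estimate_type2(pair, counts, cutoff=config.type2_cutoff,
                                seed=config.seed)
            f = out / "divergence.tsv"
            with open(f, "w") as fh:
                fh.write("metric\tvalue\n")
                fh.write(f"theta1\t{t1.theta:.4f}\n")
                fh.write(f"theta1_se\t{t1.se:.4f}\n")
                fh.write(f"lrt\t{t1.lrt:.4f}\n")
                fh.write(f"p_value\t{t1.p_value:.4g}\n")
                fh.write(f"type1_sites\t{','.join(map(str, sites1))}\n")
                fh.write(f"theta2\t{t2.theta2:.4f}\n")
                fh.write(f"type2_sites\t{','.join(map(str, t2.sites))}\n")
                fh.write(
                    "type2_radical\t"
                    + ",".join(
                        f"{c}:{t2.property_change[c][0]}>"
                        f"{t2.property_change[c][1]}"
                        for c in t2.radical_sites
                    )
                    + "\n"
                )
            record(
                "divergence",
                {"cutoff1": config.type1_cutoff, "cutoff2": config.type2_cutoff},
                [f],
            )

        if "kaks" in config.stages:
            codon_msa = read_alignment(config.codon_msa_path, codon_mode=True)
            query = config.kaks_query or codon_msa.taxa[0]
            res = sitewise_kaks(codon_msa, query)
            f = out / "kaks.tsv"
            rows = pd.DataFrame(
                {
                    "codon": np.arange(1, len(res.per_codon) + 1),
                    "omega": res.per_codon_omega,
                    "class": res.per_codon,
                }
            )
            rows.to_csv(f, sep="\t", index=False, float_format="%.4f")
            f2 = out / "kaks_summary.tsv"
            with open(f2, "w") as fh:
                fh.write("ka\tks\tomega\n")
                fh.write(f"{res.ka:.4f}\t{res.ks:.4f}\t{res.omega:.4f}\n")
            record("kaks", {"query": query}, [f, f2])

        structures = []
        if {"anm", "pca"} & set(config.stages):
            for p in config.pdb_paths:
                structures.extend(read_pdb_calpha(p))

        modes = None
        if "anm" in config.stages:
            ref = structures[0]
            model = build_hessian(ref, cutoff=config.anm_cutoff)
            modes = anm_modes(model)
            prof = mean_square_fluctuation(modes)
            f = out / "anm_profile.tsv"
            pd.DataFrame(
                {
                    "residue": np.arange(1, len(prof.msf) + 1),
                    "msf": prof.msf,
                }
            ).to_csv(f, sep="\t", index=False, float_format="%.6f")
            record("anm", {"cutoff": config.anm_cutoff}, [f])

        if "pca" in config.stages:
            from .ensemble_pca import build_ensemble

            ens = build_ensemble(
                structures, min_occupancy=config.min_occupancy
            )
            ens = iterative_superposition(ens)
            pca = ensemble_pca(ens)
            f = out / "pca_projections.tsv"
            pd.DataFrame(
                {
                    "conformer": ens.labels,
                    "pc1": pca.projections[:, 0],
                    "pc2": pca.projections[:, 1],
                    "rmsd_to_mean": ens.rmsd_to_mean,
                }
            ).to_csv(f, sep="\t", index=False, float_format="%.4f")
            files = [f]
            params = {"min_occupancy": config.min_occupancy}
            if modes is not None and modes.eigenvectors.shape[0] == 3 * ens.n_positions:
                rep = mode_overlap(pca, modes, ens=ens)
                f2 = out / "mode_overlap.tsv"
                pd.DataFrame(
                    rep.overlap,
                    index=[f"PC{i+1}" for i in range(rep.overlap.shape[0])],
                    columns=[f"ANM{j+1}" for j in range(rep.overlap.shape[1])],
                ).to_csv(f2, sep="\t", float_format="%.4f")
                files.append(f2)
            record("pca", params, files)
    except Exception as exc:
        exc.manifest = manifest  # partial manifest for post-mortem
        raise
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def demo_config(workdir, *, seed: int = 0) -> PipelineConfig:
    """Generate a fully synthetic input set and the config that runs the
    whole pipeline over it (no downloads, deterministic in the seed)."""
    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)
    tree = two_clade_tree(6)
    msa, _ = simulate_family(
        tree,
        400,
        alpha=0.5,
        cluster_b=frozenset(l for l in tree.leaf_names if l.startswith("B")),
        theta=0.3,
        shift_factor=3.0,
        seed=seed,
    )
    msa_path = work / "family.fasta"
    write_fasta(msa.sequences, msa_path)
    tree_path = work / "family.nwk"
    write_newick(tree, tree_path)
    from .synthetic_data import balanced_tree

    ctree = balanced_tree(8, 0.15)
    codon_msa, _ = simulate_codons(ctree, 120, omega_profile=0.3, seed=seed)
    codon_path = work / "codons.fasta"
    write_fasta(codon_msa.sequences, codon_path)
    base = make_ankyrin_calpha(4)
    pdb_path = work / "ankyrin.pdb"
    write_pdb_calpha([base], pdb_path)
    ens, _ = make_ensemble(
        base, "random", [2.0], M=20, rigid_noise=True, seed=seed
    )
    ens_path = work / "ensemble.pdb"
    members = [
        dataclasses.replace(
            base, id=f"conf{m+1}", coords=ens.members[m], bfactors=None
        )
        for m in range(ens.n_members)
    ]
    write_pdb_calpha(members, ens_path)
    groups = {t: ("cladeA" if t.startswith("A") else "cladeB") for t in tree.leaf_names}
    return PipelineConfig(
        output_dir=str(work / "results"),
        seed=seed,
        msa_path=str(msa_path),
        codon_msa_path=str(codon_path),
        pdb_paths=[str(pdb_path), str(ens_path)],
        tree_path=str(tree_path),
        groups=groups,
        cluster_a=[t for t in tree.leaf_names if t.startswith("A")],
        cluster_b=[t for t in tree.leaf_names if t.startswith("B")],
        kaks_query="t1",
        bootstrap_replicates=50,
    )
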