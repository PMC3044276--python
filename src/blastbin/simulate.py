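"""Deterministic synthetic fixtures with known ground truth.

Real inputs to this pipeline — BLAST tabular files against a protein
database, plus SEED/taxonomy trees and accession mapping tables — cannot
ship with a test suite, so this module fabricates all of them from one
seed.  The generator does *not* simulate sequences; it simulates BLAST
*output*, the artifact's actual input, with these guarantees:

* every read has a known true role/taxon/KO recorded in a truth table;
* the intended best hit strictly dominates all decoys by more than the
  top-percent window, so at noise 0 the pipeline must recover the truth
  exactly;
* with probability ``noise_rate`` the top hit is swapped for a reference
  annotated with a different role (a wrong best hit), degrading recovery
  accuracy roughly linearly in the noise rate;
* all randomness flows from one seeded generator — same seed, same bytes.

What it does not emulate: alignment-length/identity structure, conserved
multi-gene families (hit taxa are drawn independently), database bias, or
read-length effects.  Recovery results on fixtures therefore validate the
binning logic, not annotation accuracy on real communities.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference import Hierarchy

__all__ = ["FixtureSpec", "generate", "eight_sample_bergen_like"]


@dataclass
class FixtureSpec:
    """Shape and noise parameters of one synthetic study.

    Defaults give a small but non-degenerate world: a 3-level, 3-way
    taxonomy (27 leaf taxa), 6 subsystems x 4 roles with a quarter of the
    roles appearing in two subsystems, 60 reference proteins and 200 reads
    per sample with 1-5 hits each.
    """

    seed: int = 0
    taxonomy_depth: int = 3
    taxonomy_branching: int = 3
    n_subsystems: int = 6
    roles_per_subsystem: int = 4
    multilabel_fraction: float = 0.25
    n_refs: int = 60
    reads_per_sample: int = 200
    hits_min: int = 1
    hits_max: int = 5
    noise_rate: float = 0.0
    no_hit_rate: float = 0.02
    n_pathways: int = 4
    #: (sample name, per-role weight vector) pairs; None -> one uniform sample
    samples: list[tuple[str, Sequence[float]]] | None = None

    def __post_init__(self) -> None:
        for name, value in (
            ("multilabel_fraction", self.multilabel_fraction),
            ("noise_rate", self.noise_rate),
            ("no_hit_rate", self.no_hit_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hits_min < 1 or self.hits_max < self.hits_min:
            raise ValueError("need 1 <= hits_min <= hits_max")

    @property
    def n_roles(self) -> int:
        return self.n_subsystems * self.roles_per_subsystem

    def sample_list(self) -> list[tuple[str, np.ndarray]]:
        if self.samples is None:
            w = np.full(self.n_roles, 1.0 / self.n_roles)
            return [("s1", w)]
        out = []
        for name, weights in self.samples:
            w = np.asarray(weights, dtype=float)
            if len(w) != self.n_roles or w.min() < 0 or w.sum() == 0:
                raise ValueError(f"sample {name!r}: bad weight vector")
            out.append((name, w / w.sum()))
        return out


def _role_names(spec: FixtureSpec) -> list[str]:
    return [f"Role_{i + 1:02d}" for i in range(spec.n_roles)]


def _build_seed_tree(spec: FixtureSpec, rng: np.random.Generator):
    """SEED-style tree: root -> subsystems -> role leaves (some roles twice)."""
    roles = _role_names(spec)
    parent: dict[str, str] = {"fnroot": "fnroot"}
    label: dict[str, str] = {"fnroot": "Functional classification"}
    leaf_role: dict[str, str] = {}
    subsystems = [f"SS{i + 1}" for i in range(spec.n_subsystems)]
    for ss in subsystems:
        parent[ss] = "fnroot"
        label[ss] = f"Subsystem {ss[2:]}"
    for idx, role in enumerate(roles):
        home = idx // spec.roles_per_subsystem
        leaf = f"{subsystems[home]}.{role}"
        parent[leaf] = subsystems[home]
        label[leaf] = role
        leaf_role[leaf] = role
    n_multi = int(round(spec.multilabel_fraction * spec.n_roles))
    multi = rng.choice(spec.n_roles, size=n_multi, replace=False) if n_multi else []
    for idx in sorted(int(i) for i in np.atleast_1d(multi)):
        role = roles[idx]
        home = idx // spec.roles_per_subsystem
        other = subsystems[(home + 1) % spec.n_subsystems]
        leaf = f"{other}.{role}"
        parent[leaf] = other
        label[leaf] = role
        leaf_role[leaf] = role
    return Hierarchy(parent, label=label, leaf_role=leaf_role)


def _build_taxonomy(spec: FixtureSpec):
    """Complete b-ary taxonomy of the requested depth; ids encode the path."""
    parent: dict[str, str] = {"T": "T"}
    frontier = ["T"]
    for _ in range(spec.taxonomy_depth):
        nxt = []
        for node in frontier:
            for b in range(spec.taxonomy_branching):
                child = f"{node}.{b + 1}"
                parent[child] = node
                nxt.append(child)
        frontier = nxt
    return Hierarchy(parent), frontier  # frontier = leaf taxa


def _write_tsv(path: Path, header: str, rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def generate(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a full fixture bundle; byte-identical for identical specs.

    Emits ``seed_tree.tsv``, ``taxonomy.tsv``, ``acc2role.tsv``,
    ``acc2taxon.tsv``, ``acc2ko.tsv``, ``ko2pathway.tsv``, one
    ``<sample>.blast.tsv`` per sample, ``truth.tsv`` (read -> true
    role/taxon/KO, with NoHits rows for hitless reads) and the spec itself
    as ``fixture.cfg``.  Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    roles = _role_names(spec)
    seed_tree = _build_seed_tree(spec, rng)
    taxonomy, leaf_taxa = _build_taxonomy(spec)

    from .reference import write_hierarchy

    paths: dict[str, Path] = {}
    paths["seed_tree"] = outdir / "seed_tree.tsv"
    write_hierarchy(seed_tree, paths["seed_tree"])
    paths["taxonomy"] = outdir / "taxonomy.tsv"
    write_hierarchy(taxonomy, paths["taxonomy"])

    # one KO per role; each KO in 1-2 pathways
    ko_of_role = {role: f"K{i + 1:05d}" for i, role in enumerate(roles)}
    pathway_ids = [f"map{i + 1:03d}" for i in range(spec.n_pathways)]
    ko_pathways: dict[str, list[str]] = {}
    for role in roles:
        ko = ko_of_role[role]
        k = int(rng.integers(1, 3))
        picks = rng.choice(spec.n_pathways, size=min(k, spec.n_pathways), replace=False)
        ko_pathways[ko] = [pathway_ids[int(p)] for p in sorted(picks)]

    # references: round-robin roles first so every role has >=1 accession
    accs = [f"ACC{i + 1:04d}" for i in range(spec.n_refs)]
    ref_role: dict[str, str] = {}
    ref_taxon: dict[str, str] = {}
    for i, acc in enumerate(accs):
        role = roles[i % len(roles)] if i < len(roles) else roles[int(rng.integers(len(roles)))]
        ref_role[acc] = role
        ref_taxon[acc] = leaf_taxa[int(rng.integers(len(leaf_taxa)))]
    refs_by_role: dict[str, list[str]] = {r: [] for r in roles}
    for acc in accs:
        refs_by_role[ref_role[acc]].append(acc)

    paths["acc2role"] = outdir / "acc2role.tsv"
    _write_tsv(paths["acc2role"], "#accession\trole", [(a, ref_role[a]) for a in accs])
    paths["acc2taxon"] = outdir / "acc2taxon.tsv"
    _write_tsv(paths["acc2taxon"], "#accession\ttaxon", [(a, ref_taxon[a]) for a in accs])
    paths["acc2ko"] = outdir / "acc2ko.tsv"
    _write_tsv(paths["acc2ko"], "#accession\tko", [(a, ko_of_role[ref_role[a]]) for a in accs])
    paths["ko2pathway"] = outdir / "ko2pathway.tsv"
    _write_tsv(
        paths["ko2pathway"],
        "#ko\tpathway\tname",
        [
            (ko, pw, f"Pathway {pw[3:]}")
            for ko in sorted(ko_pathways)
            for pw in ko_pathways[ko]
        ],
    )

    truth_rows = []
    paths["samples"] = {}
    for sample, weights in spec.sample_list():
        blast_path = outdir / f"{sample}.blast.tsv"
        paths["samples"][sample] = blast_path
        with open(blast_path, "w", encoding="utf-8") as fh:
            for r in range(spec.reads_per_sample):
                read_id = f"{sample}_r{r + 1:05d}"
                if rng.random() < spec.no_hit_rate:
                    truth_rows.append((read_id, sample, "NoHits", "NoHits", "NoHits"))
                    continue
                role_idx = int(rng.choice(spec.n_roles, p=weights))
                role = roles[role_idx]
                candidates = refs_by_role[role]
                true_acc = candidates[int(rng.integers(len(candidates)))]
                truth_rows.append(
                    (read_id, sample, role, ref_taxon[true_acc], ko_of_role[role])
                )
                top_acc = true_acc
                if rng.random() < spec.noise_rate:
                    # wrong annotation: top hit from a different role
                    others = [a for a in accs if ref_role[a] != role]
                    top_acc = others[int(rng.integers(len(others)))]
                best = round(float(rng.uniform(80.0, 200.0)), 1)
                n_hits = int(rng.integers(spec.hits_min, spec.hits_max + 1))
                # decoys sit strictly below the 10% top-percent window
                decoys = []
                for _ in range(n_hits - 1):
                    acc = accs[int(rng.integers(len(accs)))]
                    score = round(float(rng.uniform(36.0, 0.85 * best)), 1)
                    decoys.append((acc, score))
                decoys.sort(key=lambda t: (-t[1], t[0]))
                for acc, score in [(top_acc, best)] + decoys:
                    ident = round(float(rng.uniform(50.0, 100.0)), 1)
                    fh.write(
                        f"{read_id}\t{acc}\t{ident}\t100\t10\t1\t1\t100\t1\t100\t"
                        f"1e-{int(rng.integers(5, 40))}\t{score}\n"
                    )

    paths["truth"] = outdir / "truth.tsv"
    _write_tsv(paths["truth"], "#read_id\tsample\trole\ttaxon\tko", truth_rows)

    paths["config"] = outdir / "fixture.cfg"
    with open(paths["config"], "w", encoding="utf-8") as fh:
        for key, value in asdict(spec).items():
            if key == "samples":
                if value is not None:
                    for name, w in value:
                        fh.write(f"sample.{name}=" + ",".join(f"{x:.6g}" for x in w) + "\n")
            else:
                fh.write(f"{key}={value}\n")
    return paths


def eight_sample_bergen_like(seed: int) -> FixtureSpec:
    """Canned spec: 4 metagenomes (DNA) + 4 metatranscriptomes (cDNA).

    Emulates a mesocosm-style paired design in shape only: the four DNA
    samples share a base role-abundance profile with mild lognormal jitter
    (sigma 0.1), while the cDNA samples are systematically shifted — half
    of the roles are 4x up-expressed before renormalization — so that
    same-condition samples are mutually closer than cross-condition pairs
    under abundance-based indices.
    """
    spec = FixtureSpec(seed=seed, reads_per_sample=250, noise_rate=0.05)
    rng = np.random.default_rng(seed ^ 0x5EED)
    base = rng.dirichlet(np.full(spec.n_roles, 2.0))
    shifted = base.copy()
    shifted[::2] *= 4.0
    shifted /= shifted.sum()
    samples: list[tuple[str, Sequence[float]]] = []
    for i in range(4):
        jitter = np.exp(rng.normal(0.0, 0.1, size=spec.n_roles))
        samples.append((f"dna{i + 1}", base * jitter))
    for i in range(4):
        jitter = np.exp(rng.normal(0.0, 0.1, size=spec.n_roles))
        samples.append((f"cdna{i + 1}", shifted * jitter))
    spec.samples = samples
    return spec
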