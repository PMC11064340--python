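"""End-to-end workflow: validate -> encode -> align -> overall NJ
(midpoint-rooted, bootstrapped) -> profiles -> iterated PNJ -> subset
NJ/MP/ML -> consensus structures -> report.

Every number in the report is recomputable from the emitted intermediate
files, and a rerun with the same seed and config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import consensus as cons_mod
from . import mp_ml, msa, seqstruct_io, trees
from .distances import distance_matrix
from .encoding import encode
from .errors import UndefinedStatisticError, UsageError, ValidationError
from .mp_ml import SubstitutionModel, empirical_frequencies
from .msa import Alignment
from .seqstruct_io import StructuredSequence


@dataclass
class PipelineConfig:
    seed: int = 0
    iterations: int = 2
    bs_threshold: float = 75.0
    replicates: int = 100
    gap_open: float = 8.0
    gap_extend: float = 1.0
    min_profile_size: int = 2
    max_profile_size: int | None = None  # None: quarter of the leaf count
    consensus_thresholds: tuple = (0.75, 1.0)
    saturation: str = "cap"
    alpha: float = 1.0
    p_inv: float = 0.0
    n_cat: int = 4


ARMS = ("seq", "seqstruct")


def validate_records(path_or_text):
    """Lenient structured-FASTA parse: (valid records, [(id, reason), ...])."""
    lines = [ln for ln in seqstruct_io._as_text(path_or_text).splitlines()
             if ln.strip()]
    if len(lines) % 3:
        raise seqstruct_io.FormatError(
            "structured FASTA must consist of 3-line records")
    records, failures, seen = [], [], set()
    for i in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[i:i + 3]
        rid = header[1:].split()[0] if header.startswith(">") else f"line{i + 1}"
        if rid in seen:
            failures.append((rid, "duplicate id"))
            continue
        seen.add(rid)
        try:
            records.append(StructuredSequence(
                id=rid, seq=seqstruct_io.normalize_seq(seq_line),
                struct=struct_line.strip()))
        except ValidationError as exc:
            failures.append((rid, str(exc)))
    return records, failures


def arm_alignment(records, arm: str, config: PipelineConfig) -> Alignment:
    """Progressive alignment of one analysis arm."""
    if arm == "seq":
        matrix = msa.default_matrix_nuc(config.gap_open, config.gap_extend)
        seqs = [(r.id, r.seq) for r in records]
    else:
        matrix = msa.default_matrix_12(config.gap_open, config.gap_extend)
        seqs = [encode(r) for r in records]
    return msa.progressive_align(seqs, matrix)


def _nj_builder(config: PipelineConfig):
    def build(aln: Alignment) -> trees.Tree:
        return trees.neighbor_joining(
            distance_matrix(aln, saturation=config.saturation))
    return build


def run_overall(records, arm: str, config: PipelineConfig, outdir) -> dict:
    """Validated records -> aligned arm -> bootstrapped, midpoint-rooted NJ."""
    if len(records) < 4:
        raise UsageError(f"fewer than 4 valid records ({len(records)})")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = arm_alignment(records, arm, config)
    aln_path = outdir / f"overall_{arm}.aln.fasta"
    seqstruct_io.write_fasta_alignment(aln, aln_path)
    dm = distance_matrix(aln, saturation=config.saturation)
    dm_path = outdir / f"overall_{arm}.dist.phy"
    dm.write_phylip(dm_path)
    supported = trees.bootstrap_support(aln, _nj_builder(config),
                                        n_reps=config.replicates,
                                        seed=config.seed)
    rooted = trees.midpoint_root(supported)
    tree_path = outdir / f"overall_{arm}.nj.nwk"
    seqstruct_io.write_newick(rooted, path=tree_path)
    return {
        "arm": arm,
        "n_records": len(records),
        "alignment": aln_path.name,
        "alignment_columns": aln.length,
        "distances": dm_path.name,
        "tree": tree_path.name,
        "average_support": round(trees.average_support(rooted), 4),
    }


def run_pnj(aln: Alignment, assignment, config: PipelineConfig, outdir,
            arm: str, overall_rooted=None) -> dict:
    """Iterated PNJ on predefined (or tree-derived) profiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if assignment is None:
        if overall_rooted is None:
            raise UsageError("need either a profile assignment or an overall tree")
        cap = config.max_profile_size or max(
            config.min_profile_size, -(-len(overall_rooted.leaves()) // 4))
        assignment = trees.profiles_from_tree(overall_rooted,
                                              min_size=config.min_profile_size,
                                              max_size=cap)
    final, audit = trees.profile_nj(aln, assignment,
                                    iterations=config.iterations,
                                    bs_threshold=config.bs_threshold,
                                    n_reps=config.replicates,
                                    seed=config.seed,
                                    saturation=config.saturation)
    rooted = _root_like_overall(final, overall_rooted,
                                members_of=audit[-1].profiles)
    bs_path = outdir / f"pnj_{arm}.bs.nwk"
    bl_path = outdir / f"pnj_{arm}.bl.nwk"
    seqstruct_io.write_newick(rooted, with_support=True, path=bs_path)
    seqstruct_io.write_newick(rooted, with_support=False, path=bl_path)
    audit_out = []
    for it in audit:
        audit_out.append({
            "iteration": it.index,
            "profiles": {n: sorted(m) for n, m in sorted(it.profiles.items())},
            "supports": {"|".join(sorted(side)): round(s, 4)
                         for side, s in sorted(it.supports.items(),
                                               key=lambda kv: sorted(kv[0]))},
            "merged": [{"super_profile": name, "from": parts}
                       for name, parts in it.merged],
        })
    return {
        "arm": arm,
        "defaults": {"iterations": config.iterations,
                     "replicates": config.replicates,
                     "bs_threshold": config.bs_threshold},
        "profiles": {n: sorted(m) for n, m in sorted(assignment.profiles.items())},
        "unassigned": sorted(assignment.unassigned),
        "n_unassigned": len(assignment.unassigned),
        "tree_bs": bs_path.name,
        "tree_bl": bl_path.name,
        "average_support": _maybe_average_support(final),
        "iterations_audit": audit_out,
    }


def _maybe_average_support(tree):
    """Mean support, or None when the tree carries no supported edge
    (e.g. a profile tree reduced to three units)."""
    try:
        return round(trees.average_support(tree), 4)
    except UndefinedStatisticError:
        return None


def _root_like_overall(tree, overall_rooted, members_of=None):
    """Root a profile tree on the edge matching the overall root bipartition.

    The overall tree's root splits its leaves in two; each profile goes to
    the side holding the majority of its members.  If that bipartition
    exists in the profile tree we root there, otherwise at the midpoint.
    """
    if overall_rooted is None or len(overall_rooted.root.children) < 2:
        return trees.midpoint_root(tree)
    sets = trees._clade_sets(overall_rooted)
    left = sets[id(overall_rooted.root.children[0])]
    profile_leaves = tree.leaf_labels()
    members_of = members_of or {}
    left_profiles = set()
    for name in profile_leaves:
        member_ids = set(members_of.get(name, [name]))
        votes = len(member_ids & left)
        if votes * 2 > len(member_ids):
            left_profiles.add(name)
    if 2 <= len(left_profiles) <= len(profile_leaves) - 2:
        target = frozenset(left_profiles)
        for node, side in trees.internal_edges(tree):
            if side == target or side == frozenset(profile_leaves) - target:
                adj = trees._unrooted_adjacency(tree)
                # split the edge above `node` at its midpoint
                par = tree.parents()[id(node)]
                length = node.length or 0.0
                adj2 = {k: [e for e in v if not (
                    (k == id(par) and e[0] is node) or
                    (k == id(node) and e[0] is par))] for k, v in adj.items()}
                entries = [(node, length / 2, node.support),
                           (par, length / 2, None)]
                return trees._build_rooted(adj2, entries)
    return trees.midpoint_root(tree)


def run_subset(records, subset_ids, config: PipelineConfig, outdir,
               reference_id: str | None = None) -> dict:
    """Re-align a chosen subset; NJ + MP + ML per arm; consensus structures."""
    if len(subset_ids) < 4:
        raise UsageError("subset must contain at least 4 taxa for MP/ML")
    by_id = {r.id: r for r in records}
    missing = [s for s in subset_ids if s not in by_id]
    if missing:
        raise UsageError(f"subset ids not in dataset: {missing}")
    subset = [by_id[s] for s in subset_ids]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"subset": sorted(subset_ids), "methods": {}}
    struct_aln = None
    for arm in ARMS:
        aln = arm_alignment(subset, arm, config)
        if arm == "seqstruct":
            struct_aln = aln
        aln_path = outdir / f"subset_{arm}.aln.fasta"
        seqstruct_io.write_fasta_alignment(aln, aln_path)
        entry = {"alignment": aln_path.name}
        # NJ with bootstrap
        nj = trees.bootstrap_support(aln, _nj_builder(config),
                                     n_reps=config.replicates, seed=config.seed)
        nj_path = outdir / f"subset_{arm}.nj.nwk"
        seqstruct_io.write_newick(trees.midpoint_root(nj), path=nj_path)
        entry["nj"] = {"tree": nj_path.name,
                       "average_support": round(trees.average_support(nj), 4)}
        # MP: NNI search + bootstrap of the search
        mp_res = mp_ml.mp_search(aln, seed=config.seed)
        mp_sup = trees.bootstrap_support(
            aln, lambda a: mp_ml.mp_search(a, seed=config.seed).tree,
            n_reps=config.replicates, seed=config.seed, reference=mp_res.tree)
        mp_path = outdir / f"subset_{arm}.mp.nwk"
        seqstruct_io.write_newick(mp_sup, path=mp_path)
        entry["mp"] = {"tree": mp_path.name, "score": mp_res.score,
                       "average_support": round(trees.average_support(mp_sup), 4)}
        # ML: GTR+I+G with empirical frequencies, equal exchangeabilities
        model = SubstitutionModel(k=len(empirical_frequencies(aln)),
                                  pi=empirical_frequencies(aln),
                                  p_inv=config.p_inv, alpha=config.alpha,
                                  n_cat=config.n_cat)
        ml_tree = mp_ml.ml_bootstrap(aln, model, n_reps=config.replicates,
                                     seed=config.seed)
        ml_path = outdir / f"subset_{arm}.ml.nwk"
        seqstruct_io.write_newick(ml_tree, path=ml_path)
        entry["ml"] = {"tree": ml_path.name,
                       "log_likelihood": round(
                           mp_ml.log_likelihood(ml_tree, aln, model), 4),
                       "average_support": round(trees.average_support(ml_tree), 4)}
        report["methods"][arm] = entry
    # consensus structures on the sequence-structure subset alignment
    report["consensus"] = {}
    for thr in config.consensus_thresholds:
        cp = cons_mod.consensus_pairs(struct_aln, threshold=thr)
        db, dropped = cons_mod.consensus_to_dotbracket(cp)
        tsv_path = outdir / f"consensus_{int(round(thr * 100))}.tsv"
        with open(tsv_path, "w", encoding="utf-8") as fh:
            fh.write("col_i\tcol_j\tfrequency\n")
            for i, j, f in cp.pairs:
                fh.write(f"{i}\t{j}\t{f:.6f}\n")
        entry = {"n_pairs": len(cp.pairs), "dotbracket": db,
                 "n_dropped_for_rendering": len(dropped), "table": tsv_path.name}
        if reference_id is not None:
            mapped, unmappable = cons_mod.map_to_reference(cp, struct_aln,
                                                           reference_id)
            entry["reference"] = {"id": reference_id, "n_mapped": len(mapped),
                                  "n_unmappable": len(unmappable)}
        report["consensus"][f"{int(round(thr * 100))}%"] = entry
    return report


def read_profiles_tsv(path) -> trees.ProfileAssignment:
    """TSV of ``profile_name<TAB>leaf_id`` lines."""
    profiles = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, leaf = line.split("\t")
            profiles.setdefault(name, []).append(leaf)
    return trees.ProfileAssignment(profiles=profiles)


def run_all(input_path_or_text, outdir, config: PipelineConfig | None = None,
            mode: str = "both", profiles=None, subset_ids=None,
            reference_id: str | None = None) -> dict:
    """The full workflow; returns (and writes) the run report."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, failures = validate_records(input_path_or_text)
    arms = ARMS if mode == "both" else (mode,)
    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "excluded": [{"id": rid, "reason": reason} for rid, reason in failures],
        "n_input": len(records) + len(failures),
        "n_valid": len(records),
        "arms": {},
    }
    for arm in arms:
        frag = run_overall(records, arm, config, outdir)
        rooted = seqstruct_io.read_newick(outdir / frag["tree"])
        aln = seqstruct_io.read_fasta_alignment(
            outdir / frag["alignment"],
            alphabet="nuc" if arm == "seq" else "encoded")
        pnj_frag = run_pnj(aln, profiles, config, outdir, arm,
                           overall_rooted=rooted)
        report["arms"][arm] = {"overall": frag, "pnj": pnj_frag}
    if subset_ids:
        report["subset"] = run_subset(records, subset_ids, config, outdir,
                                      reference_id=reference_id)
    json_path = outdir / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    lines = [f"structphy run (seed {report['seed']})",
             f"records: {report['n_valid']} valid of {report['n_input']}"]
    for item in report["excluded"]:
        lines.append(f"  excluded {item['id']}: {item['reason']}")
    for arm, frags in sorted(report.get("arms", {}).items()):
        ov, pnj = frags["overall"], frags["pnj"]
        lines.append(f"[{arm}] overall NJ: {ov['alignment_columns']} columns, "
                     f"avg support {ov['average_support']}")
        lines.append(f"[{arm}] PNJ ({pnj['defaults']['iterations']} iterations, "
                     f"{pnj['defaults']['replicates']} replicates, threshold "
                     f"{pnj['defaults']['bs_threshold']}): "
                     f"{len(pnj['profiles'])} profiles, "
                     f"{pnj['n_unassigned']} unassigned, "
                     f"avg support {pnj['average_support']}")
    for level, entry in sorted(report.get("subset", {}).get("consensus", {}).items()):
        lines.append(f"consensus {level}: {entry['n_pairs']} pairs")
    return "\n".join(lines) + "\n"
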