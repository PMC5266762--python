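"""Synthetic reference databases, evolved alignments, and simulated qPCR plates.

Every pipeline stage in this package can be exercised against data with
known ground truth and no downloads:

* :func:`generate_reference_db` emulates the structure of a clade
  coverage/specificity study — an in-group of sequences carrying planted
  primer-binding sites with a controlled per-sequence mismatch count, plus a
  non-target out-group — and records exactly what was planted.
* :func:`evolve_alignment` evolves sequences down a tree under the
  Jukes-Cantor substitution model, for distance/NJ recovery tests.
* :func:`simulate_qpcr_plate` produces plate tables from a known standard
  curve with Gaussian Ct noise, mirroring the triplicate-reactions-on-
  duplicate-extractions layout of a typical quantification experiment.

All generators are pure functions of (config, seed). Planted mismatches
substitute to a base outside the primer's IUPAC set at that position, so a
planted mismatch is a true mismatch under set-intersection matching;
background mutations never touch primer footprints.

Default conditions are study-like: an in-group of 109 sequences (the size
of the GOM Arc I clade in the SSU database release the field analysis used),
a desk-scale out-group of 200, 1600-nt templates (full-length mcrA scale),
and the McrA159F/McrA345R qPCR pair planted at its published coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import catalog
from .alphabet import MASKS, expand_random, revcomp, seq_to_masks
from .amplicon import predict_amplicons
from .coverage import CoverageTable, _table_from_minima, coverage_table, pair_coverage
from .io import GroupLabeling, NucleotideSequence, ReferenceDatabase
from .phylo import AlignedSet
from .primers import Primer, count_mismatches, window_mismatch_counts
from .qpcr import PLATE_COLUMNS, StandardCurve

__all__ = [
    "SyntheticConfig",
    "PlantedSite",
    "SequenceTruth",
    "GroundTruth",
    "ConsistencyError",
    "generate_reference_db",
    "verify_ground_truth",
    "write_bundle",
    "load_bundle",
    "evolve_alignment",
    "random_tree",
    "simulate_qpcr_plate",
    "write_plate",
    "DEFAULT_CURVE",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BITS = np.array([1, 2, 4, 8], dtype=np.uint8)  # A, C, G, T

#: ideal-efficiency default curve used by plate simulations
DEFAULT_CURVE = StandardCurve(slope=-3.3219, intercept=40.0, r_squared=1.0)


class ConsistencyError(AssertionError):
    """The emitted data contradicts its own ground-truth manifest."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for a planted-site reference database."""

    seed: int = 0
    in_group_size: int = 109
    out_group_size: int = 200
    template_length: int = 1600
    fwd_primer: Primer = catalog.MCRA_159F
    rev_primer: Primer = catalog.MCRA_345R
    fwd_start: int = 159  # 1-based start of the forward footprint
    rev_end: int = 345  # 1-based end of the reverse footprint
    background_rate: float = 0.02  # per-site substitution rate outside footprints
    #: (fraction of in-group, mismatches per primer); leftover fraction gets 0
    mismatch_schedule: tuple[tuple[float, int], ...] = (
        (0.7, 0), (0.1, 1), (0.1, 2), (0.1, 3),
    )
    out_group_policy: str = "absent"  # or "degraded"
    out_group_mismatches: int = 6  # used by the "degraded" policy
    in_group_name: str = "in_group"
    out_group_name: str = "out_group"

    def footprints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        f = (self.fwd_start, self.fwd_start + len(self.fwd_primer) - 1)
        r = (self.rev_end - len(self.rev_primer) + 1, self.rev_end)
        return f, r

    def validate(self) -> None:
        (f0, f1), (r0, r1) = self.footprints()
        if not (1 <= f0 and f1 < r0 and r1 <= self.template_length):
            raise ValueError(
                f"primer footprints {f0}-{f1} / {r0}-{r1} do not fit ordered and "
                f"within a {self.template_length}-nt template"
            )
        if self.in_group_size < 1:
            raise ValueError("in_group_size must be >= 1")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")
        if sum(f for f, _ in self.mismatch_schedule) > 1 + 1e-9:
            raise ValueError("mismatch schedule fractions sum to more than 1")
        if self.out_group_policy not in ("absent", "degraded"):
            raise ValueError("out_group_policy must be 'absent' or 'degraded'")
        for primer in (self.fwd_primer, self.rev_primer):
            plantable = sum(1 for ch in primer.seq if MASKS[ch] != 15)
            needed = [k for _, k in self.mismatch_schedule]
            if self.out_group_policy == "degraded":
                needed.append(self.out_group_mismatches)
            if max(needed, default=0) > plantable:
                raise ValueError(
                    f"cannot plant {max(needed)} mismatches in primer "
                    f"{primer.name!r} ({plantable} non-N positions)"
                )


@dataclass(frozen=True)
class PlantedSite:
    start: int
    end: int
    mismatches: int
    positions: tuple[int, ...]  # primer-relative, 1-based


@dataclass(frozen=True)
class SequenceTruth:
    seq_id: str
    group: str
    fwd_site: PlantedSite | None
    rev_site: PlantedSite | None
    product_size_reported: int | None
    product_size_inclusive: int | None
    amplicon_seq: str | None


@dataclass
class GroundTruth:
    """Everything the generator planted, plus the coverage tables it implies."""

    in_group: str
    out_group: str
    fwd_primer: Primer
    rev_primer: Primer
    sequences: dict[str, SequenceTruth]
    expected_coverage: dict[str, CoverageTable]  # fwd name, rev name, and "pair"

    def to_json(self) -> str:
        def encode(obj):
            if isinstance(obj, (PlantedSite, SequenceTruth, CoverageTable, Primer)):
                return asdict(obj)
            raise TypeError(type(obj))

        payload = {
            "in_group": self.in_group,
            "out_group": self.out_group,
            "fwd_primer": asdict(self.fwd_primer),
            "rev_primer": asdict(self.rev_primer),
            "sequences": {k: asdict(v) for k, v in self.sequences.items()},
            "expected_coverage": {
                k: asdict(v) for k, v in self.expected_coverage.items()
            },
        }
        return json.dumps(payload, indent=1, default=encode)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)

        def site(d):
            if d is None:
                return None
            return PlantedSite(d["start"], d["end"], d["mismatches"],
                               tuple(d["positions"]))

        sequences = {
            k: SequenceTruth(
                seq_id=v["seq_id"], group=v["group"],
                fwd_site=site(v["fwd_site"]), rev_site=site(v["rev_site"]),
                product_size_reported=v["product_size_reported"],
                product_size_inclusive=v["product_size_inclusive"],
                amplicon_seq=v["amplicon_seq"],
            )
            for k, v in raw["sequences"].items()
        }
        expected = {
            k: CoverageTable(
                intra_group_percent=tuple(v["intra_group_percent"]),
                out_group_hits=tuple(v["out_group_hits"]),
                in_group_size=v["in_group_size"],
                out_group_size=v["out_group_size"],
                levels=tuple(v["levels"]),
            )
            for k, v in raw["expected_coverage"].items()
        }
        return cls(
            in_group=raw["in_group"],
            out_group=raw["out_group"],
            fwd_primer=Primer(**raw["fwd_primer"]),
            rev_primer=Primer(**raw["rev_primer"]),
            sequences=sequences,
            expected_coverage=expected,
        )


def _schedule_counts(schedule: Sequence[tuple[float, int]], n: int) -> list[int]:
    """Integer per-level counts; leftover sequences get perfect (0-mismatch) sites."""
    raw = [f * n for f, _ in schedule]
    counts = [int(math.floor(x + 1e-9)) for x in raw]
    target = int(round(sum(f for f, _ in schedule) * n))
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order:
        if sum(counts) >= target:
            break
        counts[i] += 1
    return counts


def _plant_mismatches(
    seq: np.ndarray,
    pattern_mask: np.ndarray,
    footprint_start0: int,
    primer_len: int,
    reverse: bool,
    k: int,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Substitute k footprint positions to bases outside the primer's set.

    Returns the primer-relative 1-based positions planted. ``pattern_mask``
    is the + strand footprint pattern (primer masks, rev-comped for reverse
    primers); positions where the pattern is N cannot hold a mismatch.
    """
    plantable = [j for j in range(1, primer_len + 1)
                 if pattern_mask[(primer_len - j) if reverse else (j - 1)] != 15]
    chosen = sorted(
        int(j) for j in rng.choice(np.array(plantable), size=k, replace=False)
    ) if k else []
    for j in chosen:
        offset = (primer_len - j) if reverse else (j - 1)
        site_mask = int(pattern_mask[offset])
        candidates = [b for b in range(4) if not (int(_BITS[b]) & site_mask)]
        seq[footprint_start0 + offset] = candidates[int(rng.integers(len(candidates)))]
    return tuple(chosen)


def generate_reference_db(
    config: SyntheticConfig,
) -> tuple[ReferenceDatabase, GroundTruth]:
    """Labeled database with planted primer sites plus its ground-truth manifest.

    Deterministic under ``config.seed``. The in-group shares one concrete
    realization of each (possibly degenerate) primer site planted in a random
    ancestor; each member then receives independent background substitutions
    outside the footprints and its scheduled number of true mismatches inside
    them. Out-group sequences either lack the sites entirely ("absent") or
    carry both sites degraded by a fixed mismatch count ("degraded").
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fwd, rev = config.fwd_primer, config.rev_primer
    L = config.template_length
    (f0, f1), (r0, r1) = config.footprints()

    ancestor = rng.integers(0, 4, size=L).astype(np.int64)
    fwd_site_seq = expand_random(fwd.seq, rng)  # concrete, shared by the clade
    rev_site_seq = revcomp(expand_random(rev.seq, rng))  # + strand pattern
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    ancestor[f0 - 1 : f1] = [base_index[c] for c in fwd_site_seq]
    ancestor[r0 - 1 : r1] = [base_index[c] for c in rev_site_seq]

    fwd_mask = seq_to_masks(fwd.seq)
    rev_mask = seq_to_masks(revcomp(rev.seq))
    footprint = np.zeros(L, dtype=bool)
    footprint[f0 - 1 : f1] = True
    footprint[r0 - 1 : r1] = True
    background_ok = np.flatnonzero(~footprint)

    counts = _schedule_counts(config.mismatch_schedule, config.in_group_size)
    mm_per_seq = []
    for (frac, k), c in zip(config.mismatch_schedule, counts):
        mm_per_seq.extend([k] * c)
    mm_per_seq.extend([0] * (config.in_group_size - len(mm_per_seq)))

    records: list[NucleotideSequence] = []
    labels: dict[str, str] = {}
    sequences: dict[str, SequenceTruth] = {}

    def finish(seq_arr: np.ndarray) -> str:
        return _BASES[seq_arr].tobytes().decode("ascii")

    width = max(4, len(str(max(config.in_group_size, config.out_group_size))))
    for idx, k in enumerate(mm_per_seq):
        seq = ancestor.copy()
        mutate = background_ok[rng.random(background_ok.size) < config.background_rate]
        seq[mutate] = (seq[mutate] + rng.integers(1, 4, size=mutate.size)) % 4
        fwd_pos = _plant_mismatches(seq, fwd_mask, f0 - 1, len(fwd), False, k, rng)
        rev_pos = _plant_mismatches(seq, rev_mask, r0 - 1, len(rev), True, k, rng)
        sid = f"{config.in_group_name}_{idx + 1:0{width}d}"
        text = finish(seq)
        records.append(NucleotideSequence(sid, text))
        labels[sid] = config.in_group_name
        sequences[sid] = SequenceTruth(
            seq_id=sid,
            group=config.in_group_name,
            fwd_site=PlantedSite(f0, f1, k, fwd_pos),
            rev_site=PlantedSite(r0, r1, k, rev_pos),
            product_size_reported=r1 - f0,
            product_size_inclusive=r1 - f0 + 1,
            amplicon_seq=text[f0 - 1 : r1],
        )

    for idx in range(config.out_group_size):
        sid = f"{config.out_group_name}_{idx + 1:0{width}d}"
        if config.out_group_policy == "absent":
            seq = rng.integers(0, 4, size=L).astype(np.int64)
            truth = SequenceTruth(sid, config.out_group_name, None, None,
                                  None, None, None)
        else:
            k = config.out_group_mismatches
            seq = ancestor.copy()
            mutate = background_ok[
                rng.random(background_ok.size) < config.background_rate
            ]
            seq[mutate] = (seq[mutate] + rng.integers(1, 4, size=mutate.size)) % 4
            fwd_pos = _plant_mismatches(seq, fwd_mask, f0 - 1, len(fwd), False, k, rng)
            rev_pos = _plant_mismatches(seq, rev_mask, r0 - 1, len(rev), True, k, rng)
            truth = SequenceTruth(
                sid, config.out_group_name,
                PlantedSite(f0, f1, k, fwd_pos), PlantedSite(r0, r1, k, rev_pos),
                r1 - f0, r1 - f0 + 1, None,
            )
        records.append(NucleotideSequence(sid, finish(seq)))
        labels[sid] = config.out_group_name
        sequences[sid] = truth

    in_minima: list[int | None] = [k for k in mm_per_seq]
    if config.out_group_policy == "absent":
        out_minima: list[int | None] = [None] * config.out_group_size
    else:
        out_minima = [config.out_group_mismatches] * config.out_group_size
    expected = {
        fwd.name: _table_from_minima(in_minima, out_minima, 3),
        rev.name: _table_from_minima(in_minima, out_minima, 3),
        "pair": _table_from_minima(in_minima, out_minima, 3),
    }

    db = ReferenceDatabase(
        records, GroupLabeling(labels, in_group=config.in_group_name)
    )
    truth = GroundTruth(
        in_group=config.in_group_name,
        out_group=config.out_group_name,
        fwd_primer=fwd,
        rev_primer=rev,
        sequences=sequences,
        expected_coverage=expected,
    )
    return db, truth


def verify_ground_truth(
    db: ReferenceDatabase, truth: GroundTruth, max_mm: int = 3
) -> dict[str, int]:
    """Run the real pipeline on emitted data and check every ground-truth claim.

    Raises :class:`ConsistencyError` on the first contradiction; returns a
    small summary dict (counts of checks performed) on success.
    """
    fwd, rev = truth.fwd_primer, truth.rev_primer
    by_id = {r.id: r for r in db.records}
    n_sites = n_amplicons = 0
    for sid, st in truth.sequences.items():
        rec = by_id.get(sid)
        if rec is None:
            raise ConsistencyError(f"{sid}: in manifest but not in database")
        for primer, site, reverse in ((fwd, st.fwd_site, False),
                                      (rev, st.rev_site, True)):
            if site is None:
                continue
            window = rec.seq[site.start - 1 : site.end]
            if reverse:
                window = revcomp(window)
            mm, pos = count_mismatches(primer, window)
            if mm != site.mismatches or tuple(pos) != site.positions:
                raise ConsistencyError(
                    f"{sid}/{primer.name}: planted {site.mismatches} at "
                    f"{site.positions}, scan found {mm} at {tuple(pos)}"
                )
            counts = window_mismatch_counts(primer, rec.seq)
            if int(counts.min()) != site.mismatches:
                raise ConsistencyError(
                    f"{sid}/{primer.name}: a better off-site footprint exists "
                    f"({int(counts.min())} < {site.mismatches})"
                )
            n_sites += 1
        if (
            st.amplicon_seq is not None
            and st.fwd_site is not None
            and st.fwd_site.mismatches <= max_mm
            and st.rev_site.mismatches <= max_mm
        ):
            preds = predict_amplicons(fwd, rev, rec, max_mismatches=max_mm)
            if len(preds) != 1:
                raise ConsistencyError(
                    f"{sid}: expected exactly 1 amplicon, predicted {len(preds)}"
                )
            p = preds[0]
            if (
                p.amplicon_seq != st.amplicon_seq
                or p.product_size_reported != st.product_size_reported
                or p.product_size_inclusive != st.product_size_inclusive
                or p.fwd_hit.start != st.fwd_site.start
                or p.rev_hit.end != st.rev_site.end
            ):
                raise ConsistencyError(f"{sid}: predicted amplicon != planted amplicon")
            n_amplicons += 1

    observed = {
        fwd.name: coverage_table(fwd, db, in_group=truth.in_group, max_mm=max_mm),
        rev.name: coverage_table(rev, db, in_group=truth.in_group, max_mm=max_mm),
        "pair": pair_coverage(fwd, rev, db, in_group=truth.in_group, max_mm=max_mm),
    }
    for key, expected in truth.expected_coverage.items():
        got = observed[key]
        if (
            tuple(round(x, 9) for x in got.intra_group_percent)
            != tuple(round(x, 9) for x in expected.intra_group_percent)
            or got.out_group_hits != expected.out_group_hits
        ):
            raise ConsistencyError(
                f"coverage[{key}]: observed {got} != expected {expected}"
            )
    return {"sites_checked": n_sites, "amplicons_checked": n_amplicons,
            "coverage_tables_checked": len(truth.expected_coverage)}


def write_bundle(
    db: ReferenceDatabase, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write reference.fasta, labels.tsv and ground_truth.json into a directory."""
    from .io import write_fasta, write_labels

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "labels": outdir / "labels.tsv",
        "manifest": outdir / "ground_truth.json",
    }
    write_fasta(db.records, paths["fasta"])
    write_labels(db.labels, paths["labels"])
    paths["manifest"].write_text(truth.to_json())
    return paths


def load_bundle(outdir: str | Path) -> tuple[ReferenceDatabase, GroundTruth]:
    from .io import read_fasta, read_labels

    outdir = Path(outdir)
    truth = GroundTruth.from_json((outdir / "ground_truth.json").read_text())
    records = read_fasta(outdir / "reference.fasta")
    labels = read_labels(outdir / "labels.tsv", in_group=truth.in_group)
    return ReferenceDatabase(records, labels), truth


# ---------------------------------------------------------------------------
# sequence evolution under Jukes-Cantor


def _jc_mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One JC edge: each site differs with probability (3/4)(1 - e^(-4d/3))."""
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p_change)
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def evolve_alignment(
    tree: TreeNode | str, root_length: int, seed: int
) -> AlignedSet:
    """Evolve an ungapped alignment down a tree under the JC model.

    Branch lengths are expected substitutions per site; the root sequence is
    uniform random of length ``root_length``. Leaves appear in tree tip order.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(StringIO(tree))
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            raise ValueError(
                f"every edge needs a non-negative length (node {node.name!r})"
            )
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=root_length).astype(np.int64)
    seqs: dict[int, np.ndarray] = {id(tree): root_seq}
    ids, rows = [], []
    for node in tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        seqs[id(node)] = _jc_mutate(parent_seq, float(node.length), rng)
        if node.is_tip():
            ids.append(node.name)
            rows.append(_BASES[seqs[id(node)]].tobytes().decode("ascii"))
    return AlignedSet(ids=ids, seqs=rows)


def random_tree(
    n_leaves: int,
    seed: int | np.random.Generator,
    pendant_range: tuple[float, float] = (0.04, 0.15),
    internal_range: tuple[float, float] = (0.02, 0.06),
) -> TreeNode:
    """A random binary tree with leaves t1..tn and uniform-drawn branch lengths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    nodes = [TreeNode(name=f"t{i + 1}") for i in range(n_leaves)]
    for leaf in nodes:
        leaf.length = float(rng.uniform(*pendant_range))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(*internal_range))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return TreeNode(children=nodes)


# ---------------------------------------------------------------------------
# qPCR plate simulation


def simulate_qpcr_plate(
    true_copies: Mapping[str, float],
    curve: StandardCurve = DEFAULT_CURVE,
    sigma_ct: float = 0.2,
    reps: int = 3,
    extractions: int = 2,
    seed: int = 0,
    standards: Sequence[float] = tuple(10.0 ** k for k in range(1, 8)),
    standard_reps: int = 3,
) -> pd.DataFrame:
    """Simulated plate: noisy standards plus unknowns at known copy numbers.

    Each unknown sample gets ``reps`` reactions on each of ``extractions``
    DNA extractions (the default 3 x 2 mirrors triplicate reactions on
    duplicate extractions). Ct = slope*log10(copies) + intercept + N(0, sigma);
    non-positive copy numbers produce "ND" (non-detect) rows.
    """
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for copies in standards:
        base_ct = curve.slope * math.log10(copies) + curve.intercept
        for rep in range(1, standard_reps + 1):
            ct = base_ct + rng.normal(0.0, sigma_ct)
            rows.append(("standard", "std", rep, "standard", copies, ct, False))
    for sample, copies in true_copies.items():
        for ext in range(1, extractions + 1):
            for rep in range(1, reps + 1):
                if copies <= 0:
                    rows.append((sample, f"e{ext}", rep, "unknown",
                                 np.nan, np.nan, True))
                else:
                    ct = (curve.slope * math.log10(copies) + curve.intercept
                          + rng.normal(0.0, sigma_ct))
                    rows.append((sample, f"e{ext}", rep, "unknown",
                                 np.nan, ct, False))
    return pd.DataFrame(
        rows, columns=["sample", "extraction", "replicate", "role",
                       "known_copies", "ct", "nd"],
    )


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    """Write a plate table as TSV, rendering non-detects as 'ND'."""
    out = plate.copy()
    out["ct"] = [
        "ND" if nd else f"{ct:.10g}" for ct, nd in zip(out["ct"], out["nd"])
    ]
    out[PLATE_COLUMNS].to_csv(path, sep="\t", index=False)
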