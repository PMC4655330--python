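"""Ground-truthed synthetic inputs for every analysis in the package.

Three generators, all bit-reproducible from (spec, seed):

* :func:`generate_plastome` — a circular plastome assembled as
  LSC + IRa + SSC + revcomp(IRa), with planted repeats of each class and
  gene stubs. Defaults mimic a mimosoid-scale genome: 160–175 kb total,
  GC ≈ 35.5 %, IR of 25–40 kb. The bases flanking each planted IR copy are
  forced to mismatch their inverted partners so the planted IR is the
  *maximal* inverted pair and boundary recovery is exactly defined.
* :func:`evolve_alignment` — sequences evolved along a tree under GTR+Γ
  with an optional insertion/deletion process (geometric lengths, mean 3,
  rate expressed relative to the substitution rate), emitting the true
  alignment with gap columns plus per-branch event counts.
* :func:`evolve_codon_alignment` — codon sequences under a GY94-style model
  with known per-branch ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._likelihood import ReversibleModel, discrete_gamma_rates, gtr_rate_matrix
from .alignment import Alignment
from .codon_rates import CodonAlignment, SENSE_CODONS, codon_rate_matrix
from .intervals import CircularInterval
from .plastome_io import AnnotatedPlastome, GeneFeature, reverse_complement
from .trees import Node, PhyloTree

__all__ = [
    "PlantedRepeat",
    "GeneStub",
    "PlastomeSpec",
    "SimTruth",
    "generate_plastome",
    "evolve_alignment",
    "evolve_codon_alignment",
    "random_clock_tree",
]


def random_clock_tree(n_taxa: int, height: float, seed: int = 0, prefix: str = "t") -> PhyloTree:
    """A random ultrametric (strict-clock) tree of total height ``height``.

    Built by recursive random bisection with split depths drawn uniformly;
    every root-to-tip path length equals ``height`` exactly.
    """
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i}" for i in range(n_taxa)]

    def attach(parent: Node, names: list[str], depth: float) -> None:
        """Hang a subtree of total height ``depth`` for ``names`` under ``parent``."""
        if len(names) == 1:
            child = Node(name=names[0], length=depth)
        else:
            edge = depth * float(rng.uniform(0.2, 0.8))
            child = Node(length=edge)
            split = int(rng.integers(1, len(names)))
            attach(child, names[:split], depth - edge)
            attach(child, names[split:], depth - edge)
        child.parent = parent
        parent.children.append(child)

    root = Node()
    split = max(1, n_taxa // 2)
    attach(root, labels[:split], height)
    attach(root, labels[split:], height)
    return PhyloTree(root)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class PlantedRepeat:
    """One repeat to plant: klass in {mono, tandem, dispersed}.

    * mono: ``unit`` is the base, ``copies`` the run length.
    * tandem: ``unit`` is the repeat unit, ``copies`` the copy count.
    * dispersed: ``unit`` is the segment (or its length via ``copies`` of a
      random segment when empty), planted at ``position`` and ``position2``;
      ``orientation`` direct/inverted.
    """

    klass: str
    region: str  # LSC | IR | SSC
    position: int  # offset within the region
    unit: str = ""
    copies: int = 1
    position2: int | None = None
    region2: str | None = None
    orientation: str = "direct"
    divergence: float = 0.0  # per-base substitution probability applied to copies


@dataclass(frozen=True)
class GeneStub:
    name: str
    region: str
    position: int
    length: int
    strand: int = 1
    kind: str = "protein"


@dataclass
class PlastomeSpec:
    """Recipe for one synthetic plastome."""

    lsc_len: int = 88000
    ir_len: int = 26000
    ssc_len: int = 18000
    at_fraction: float = 0.645  # GC ~ 35.5 %
    planted: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    seed: int = 0
    accession: str = "SYN000001"


@dataclass
class SimTruth:
    """Ground truth accompanying a synthetic dataset."""

    ir_a: CircularInterval | None = None
    ir_b: CircularInterval | None = None
    region_intervals: dict = field(default_factory=dict)
    planted_repeats: list = field(default_factory=list)  # (PlantedRepeat, genome spans)
    tree: PhyloTree | None = None
    branch_events: dict = field(default_factory=dict)
    per_branch_omega: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, at_fraction: float) -> np.ndarray:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return rng.choice(_BASES, size=n, p=[p_at, p_gc, p_gc, p_at])


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_plastome(spec: PlastomeSpec) -> tuple[AnnotatedPlastome, SimTruth]:
    """Assemble a circular plastome with planted structure and repeats."""
    rng = np.random.default_rng(spec.seed)
    regions = {
        "LSC": _random_seq(rng, spec.lsc_len, spec.at_fraction),
        "IR": _random_seq(rng, spec.ir_len, spec.at_fraction),
        "SSC": _random_seq(rng, spec.ssc_len, spec.at_fraction),
    }

    region_offsets = {
        "LSC": 0,
        "IR": spec.lsc_len,  # IRa
        "SSC": spec.lsc_len + spec.ir_len,
    }
    occupied: dict[str, list[tuple[int, int]]] = {r: [] for r in regions}
    truth = SimTruth()

    def claim(region: str, start: int, length: int, what: str) -> None:
        if start < 0 or start + length > regions[region].size:
            raise ValueError(f"planted {what} does not fit in {region} at {start}")
        for s, e in occupied[region]:
            if start < e and s < start + length:
                raise ValueError(f"planted {what} overlaps another planted feature in {region}")
        occupied[region].append((start, start + length))

    for rep in spec.planted:
        spans = []
        if rep.klass == "mono":
            run = rep.unit * rep.copies
            claim(rep.region, rep.position, len(run), "mono repeat")
            arr = np.frombuffer(run.encode(), dtype=np.uint8)
            regions[rep.region][rep.position : rep.position + len(run)] = arr
            # block accidental extension of the run
            for flank in (rep.position - 1, rep.position + len(run)):
                if 0 <= flank < regions[rep.region].size and chr(regions[rep.region][flank]) == rep.unit:
                    others = [b for b in "ACGT" if b != rep.unit]
                    regions[rep.region][flank] = ord(rng.choice(others))
            spans.append((region_offsets[rep.region] + rep.position, region_offsets[rep.region] + rep.position + len(run)))
        elif rep.klass == "tandem":
            array_seq = rep.unit * rep.copies
            arr = np.frombuffer(array_seq.encode(), dtype=np.uint8)
            arr = _mutate(rng, arr, rep.divergence)
            claim(rep.region, rep.position, arr.size, "tandem array")
            regions[rep.region][rep.position : rep.position + arr.size] = arr
            spans.append((region_offsets[rep.region] + rep.position, region_offsets[rep.region] + rep.position + arr.size))
        elif rep.klass == "dispersed":
            seg = rep.unit or "".join(chr(b) for b in _random_seq(rng, rep.copies, spec.at_fraction))
            arr = np.frombuffer(seg.encode(), dtype=np.uint8)
            claim(rep.region, rep.position, arr.size, "dispersed repeat (copy 1)")
            regions[rep.region][rep.position : rep.position + arr.size] = arr
            second = _mutate(rng, arr, rep.divergence)
            if rep.orientation == "inverted":
                second = np.frombuffer(
                    reverse_complement(second.tobytes().decode()).encode(), dtype=np.uint8
                ).copy()
            region2 = rep.region2 or rep.region
            assert rep.position2 is not None, "dispersed repeat needs position2"
            claim(region2, rep.position2, second.size, "dispersed repeat (copy 2)")
            regions[region2][rep.position2 : rep.position2 + second.size] = second
            spans.append((region_offsets[rep.region] + rep.position, region_offsets[rep.region] + rep.position + arr.size))
            spans.append((region_offsets[region2] + rep.position2, region_offsets[region2] + rep.position2 + second.size))
        else:
            raise ValueError(f"unknown planted repeat class {rep.klass!r}")
        truth.planted_repeats.append((rep, spans))

    # Assemble circle: LSC + IRa + SSC + revcomp(IRa)
    ira = regions["IR"]
    irb = np.frombuffer(reverse_complement(ira.tobytes().decode()).encode(), dtype=np.uint8).copy()
    seq = np.concatenate([regions["LSC"], ira, regions["SSC"], irb])
    n = seq.size

    ir_a = CircularInterval(spec.lsc_len, spec.ir_len, n)
    ir_b = CircularInterval(spec.lsc_len + spec.ir_len + spec.ssc_len, spec.ir_len, n)

    # Make the planted IR maximal: each flank base must mismatch its inverted partner.
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    flank_pairs = [
        (ir_a.start - 1, ir_b.end_unwrapped % n),  # LSC side of IRa vs LSC side of IRb
        (ir_a.end_unwrapped, ir_b.start - 1),  # SSC side
    ]
    for left, right in flank_pairs:
        left %= n
        right %= n
        if comp[chr(seq[left])] == chr(seq[right]):
            others = [b for b in "ACGT" if comp[b] != chr(seq[right])]
            seq[left] = ord(others[rng.integers(len(others))])

    features = []
    for stub in spec.genes:
        if stub.region == "IRb":
            offset = spec.lsc_len + spec.ir_len + spec.ssc_len
        elif stub.region in ("IR", "IRa"):
            offset = spec.lsc_len
        elif stub.region == "SSC":
            offset = spec.lsc_len + spec.ir_len
        else:
            offset = 0
        start = (offset + stub.position) % n
        features.append(
            GeneFeature(
                name=stub.name,
                kind=stub.kind,
                strand=stub.strand,
                interval=CircularInterval(start, stub.length, n),
            )
        )

    plastome = AnnotatedPlastome(id=spec.accession, sequence=seq.tobytes().decode(), features=features)
    truth.ir_a, truth.ir_b = ir_a, ir_b
    truth.region_intervals = {
        "LSC": CircularInterval(0, spec.lsc_len, n),
        "IRa": ir_a,
        "SSC": CircularInterval(spec.lsc_len + spec.ir_len, spec.ssc_len, n),
        "IRb": ir_b,
    }
    return plastome, truth


# ---------------------------------------------------------------------------
# sequence evolution along a tree


def _default_gtr() -> tuple[np.ndarray, np.ndarray]:
    exch = np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0])  # mild transition bias
    freqs = np.array([0.32, 0.18, 0.18, 0.32])  # AT-rich plastid composition
    return exch, freqs


def evolve_alignment(
    tree: PhyloTree,
    n_sites: int,
    seed: int = 0,
    exchangeabilities: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    alpha: float | None = 1.0,
    indel_rate: float = 0.0,
    indel_mean_length: float = 3.0,
    n_categories: int = 4,
) -> tuple[Alignment, SimTruth]:
    """Evolve sequences on ``tree`` under GTR+Γ with an optional indel process.

    ``indel_rate`` is relative to the substitution rate (events per site per
    substitution per site); lengths are geometric with the given mean, and
    insertions/deletions are placed uniformly. Substitutions are applied via
    the exact transition matrix per branch; indel events are Poisson per
    branch. ``alpha=None`` disables among-site rate variation.
    """
    rng = np.random.default_rng(seed)
    if exchangeabilities is None or freqs is None:
        d_exch, d_freqs = _default_gtr()
        exchangeabilities = exchangeabilities if exchangeabilities is not None else d_exch
        freqs = freqs if freqs is not None else d_freqs
    model = ReversibleModel(gtr_rate_matrix(exchangeabilities, freqs), freqs)
    if alpha is None:
        site_rates = np.ones(n_sites)
    else:
        cat_rates = discrete_gamma_rates(alpha, n_categories)
        site_rates = cat_rates[rng.integers(n_categories, size=n_sites)]

    # Global alignment bookkeeping: every site (ancestral or inserted) is a
    # column id; `column_order` keeps ids in alignment order.
    column_order: list[int] = list(range(n_sites))
    next_id = n_sites
    truth = SimTruth(tree=tree)
    leaf_seqs: dict[str, dict[int, int]] = {}

    root_states = rng.choice(4, size=n_sites, p=freqs)
    root_sites = list(range(n_sites))

    geom_p = 1.0 / indel_mean_length if indel_mean_length > 0 else 1.0

    def evolve_branch(sites: list[int], states: np.ndarray, node: Node):
        nonlocal next_id
        t = node.length
        new_sites = list(sites)
        rates_here = np.array([site_rates[s] if s < n_sites else 1.0 for s in new_sites])
        # substitutions: exact P(r_s * t) per site, sampled by (rate, state) group
        new_states = states.copy()
        for r in np.unique(rates_here):
            P = model.transition_matrix(r * t)
            cdf = np.cumsum(P, axis=1)
            idx = np.flatnonzero(rates_here == r)
            for s in range(4):
                sel = idx[states[idx] == s]
                if sel.size:
                    new_states[sel] = np.searchsorted(cdf[s], rng.random(sel.size))
        n_sub = int((new_states != states).sum())
        n_ins = n_del = 0
        if indel_rate > 0 and t > 0 and new_sites:
            lam = indel_rate * t * len(new_sites)
            for _ in range(rng.poisson(lam)):
                length = int(rng.geometric(geom_p))
                if rng.random() < 0.5 and len(new_sites) > length:  # deletion
                    pos = int(rng.integers(0, len(new_sites) - length + 1))
                    del new_sites[pos : pos + length]
                    new_states = np.delete(new_states, slice(pos, pos + length))
                    n_del += 1
                else:  # insertion
                    pos = int(rng.integers(0, len(new_sites) + 1))
                    ins_ids = list(range(next_id, next_id + length))
                    next_id += length
                    anchor_order_idx = (
                        column_order.index(new_sites[pos - 1]) + 1 if pos > 0 else 0
                    )
                    column_order[anchor_order_idx:anchor_order_idx] = ins_ids
                    ins_states = rng.choice(4, size=length, p=freqs)
                    new_sites[pos:pos] = ins_ids
                    new_states = np.concatenate([new_states[:pos], ins_states, new_states[pos:]])
                    n_ins += 1
        key = node.name or f"node{node.index}"
        truth.branch_events[key] = {"substitutions": n_sub, "insertions": n_ins, "deletions": n_del}
        return new_sites, new_states

    def walk(node: Node, sites: list[int], states: np.ndarray):
        if node.is_leaf:
            leaf_seqs[node.name] = dict(zip(sites, (int(s) for s in states)))
            return
        for child in node.children:
            c_sites, c_states = evolve_branch(sites, states, child)
            walk(child, c_sites, c_states)

    walk(tree.root, root_sites, root_states)

    bases = "ACGT"
    rows = []
    taxa = tree.taxa
    for taxon in taxa:
        present = leaf_seqs[taxon]
        rows.append("".join(bases[present[c]] if c in present else "-" for c in column_order))
    aln = Alignment(taxa=list(taxa), rows=rows, gene="sim")
    return aln, truth


def evolve_codon_alignment(
    tree: PhyloTree,
    kappa: float,
    omega_by_branch: dict | float,
    n_codons: int,
    seed: int = 0,
    pi: np.ndarray | None = None,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve codon sequences under GY94 with known per-branch ω.

    ``omega_by_branch`` maps branch keys (leaf name for terminals, sorted
    "|"-joined leaf sets for internal branches) to ω; a bare float applies
    tree-wide. Unlisted branches default to the float ``omega_by_branch`` or
    0.2.
    """
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = np.ones(61) / 61.0
    default_omega = omega_by_branch if isinstance(omega_by_branch, (int, float)) else 0.2
    omega_map = omega_by_branch if isinstance(omega_by_branch, dict) else {}

    truth = SimTruth(tree=tree)

    def branch_key(node: Node) -> str:
        if node.is_leaf:
            return node.name
        return "|".join(sorted(_leaves_under(node)))

    def _leaves_under(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        out = []
        for c in node.children:
            out.extend(_leaves_under(c))
        return out

    models: dict[float, ReversibleModel] = {}

    def model_for(w: float) -> ReversibleModel:
        if w not in models:
            models[w] = ReversibleModel(codon_rate_matrix(kappa, w, pi), pi, normalize=False)
        return models[w]

    root_states = rng.choice(61, size=n_codons, p=pi)
    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: Node, states: np.ndarray):
        if node.is_leaf:
            leaf_states[node.name] = states
            return
        for child in node.children:
            w = float(omega_map.get(branch_key(child), default_omega))
            truth.per_branch_omega[branch_key(child)] = w
            P = model_for(w).transition_matrix(child.length)
            cdf = np.cumsum(P, axis=1)
            new = states.copy()
            for s in np.unique(states):
                sel = np.flatnonzero(states == s)
                new[sel] = np.searchsorted(cdf[s], rng.random(sel.size))
            walk(child, new)

    walk(tree.root, root_states)
    rows = ["".join(SENSE_CODONS[s] for s in leaf_states[t]) for t in tree.taxa]
    aln = CodonAlignment(taxa=list(tree.taxa), rows=rows, gene="sim")
    return aln, truth
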