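"""Cross-species miRNA target-site conservation and gain/loss mapping.

For a set of orthologous transcripts the same anchor miRNA locates the
best-scoring site window in each species; sites are compared against a
reference species (substitutions counted with the bulged nucleotide
excluded) and classified retained/lost by a penalty threshold. Presence /
absence of the site is then mapped onto a species tree by Fitch small
parsimony to count the minimum number of gain and loss events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .duplex import Duplex, PenaltyScheme, TargetSite, scan_targets, score_duplex
from .seqio import NucSeq


@dataclass(frozen=True)
class SiteRecord:
    window: NucSeq
    transcript_id: str
    interval: tuple[int, int]
    duplex: Duplex
    score: float


@dataclass(frozen=True)
class OrthologSiteSet:
    mirna: NucSeq
    sites: dict[str, SiteRecord]
    reference_species: str

    def __post_init__(self) -> None:
        if self.reference_species not in self.sites:
            raise ValueError(
                f"reference species {self.reference_species!r} missing from site set"
            )


def extract_site(
    mirna: NucSeq,
    transcript: NucSeq,
    scheme: PenaltyScheme | None = None,
) -> SiteRecord:
    """Best-scoring window for the miRNA anywhere on the transcript.

    No cutoff is applied: the ortholog site is located even when degenerate.
    """
    scheme = scheme or PenaltyScheme()
    sites = scan_targets(mirna, transcript, scheme, cutoff=math.inf)
    best = sites[0]
    return SiteRecord(
        window=transcript.subseq(*best.interval),
        transcript_id=transcript.id,
        interval=best.interval,
        duplex=best.duplex,
        score=best.score,
    )


def build_site_set(
    mirna: NucSeq,
    transcripts: Mapping[str, NucSeq],
    reference_species: str,
    scheme: PenaltyScheme | None = None,
) -> OrthologSiteSet:
    sites = {
        sp: extract_site(mirna, tr, scheme) for sp, tr in transcripts.items()
    }
    return OrthologSiteSet(mirna, sites, reference_species)


@dataclass
class ConservationReport:
    """Per-species site score, substitution count and retained/lost status."""

    table: pd.DataFrame
    loss_threshold: float
    reference_species: str
    scheme: PenaltyScheme

    @property
    def summary(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    def to_tsv(self) -> str:
        header = (
            f"# loss_threshold={self.loss_threshold:g} "
            f"reference={self.reference_species} "
            f"scheme=mm:{self.scheme.mismatch_penalty:g},"
            f"gu:{self.scheme.gu_penalty:g},"
            f"bulge:{self.scheme.bulge_penalty_per_nt:g},"
            f"core:{self.scheme.core_range[0]}-{self.scheme.core_range[1]}"
            f"x{self.scheme.core_multiplier:g}\n"
        )
        return header + self.table.to_csv(sep="\t", index=False)


def _site_by_mirna_position(rec: SiteRecord, mirna_len: int) -> list[str]:
    """Target base facing each miRNA position ('-' where the miRNA bulges).

    Bulged *target* nucleotides carry no miRNA position and therefore drop
    out: comparisons across species are bulge-excluded by construction.
    """
    window = rec.window.seq
    mapping = rec.duplex.mirna_to_target_base("N" * mirna_len, window)
    return [mapping.get(i, "-") for i in range(1, mirna_len + 1)]


def build_report(
    sites: OrthologSiteSet,
    scheme: PenaltyScheme | None = None,
    loss_threshold: float = 4.0,
) -> ConservationReport:
    """Score each species' site and compare it to the reference.

    ``substitutions`` counts differences at miRNA-anchored positions with
    bulged nucleotides excluded; ``substitutions_raw`` additionally counts
    positions where only one of the two duplexes bulges. Status is
    ``retained`` when the penalty score is at or below ``loss_threshold``.
    """
    scheme = scheme or PenaltyScheme()
    if len(sites.sites) < 2:
        raise ValueError("need at least two species")
    mlen = len(sites.mirna)
    ref = _site_by_mirna_position(sites.sites[sites.reference_species], mlen)
    rows = []
    for sp in sorted(sites.sites):
        rec = sites.sites[sp]
        assert abs(rec.score - score_duplex(rec.duplex.pairs, scheme)) < 1e-9
        own = _site_by_mirna_position(rec, mlen)
        subs = sum(
            1 for a, b in zip(own, ref) if a != "-" and b != "-" and a != b
        )
        raw = subs + sum(1 for a, b in zip(own, ref) if (a == "-") != (b == "-"))
        rows.append(
            {
                "species": sp,
                "transcript": rec.transcript_id,
                "start": rec.interval[0],
                "end": rec.interval[1],
                "site": rec.window.seq,
                "score": rec.score,
                "substitutions": subs,
                "substitutions_raw": raw,
                "status": "retained" if rec.score <= loss_threshold else "lost",
            }
        )
    table = pd.DataFrame(rows)
    return ConservationReport(table, loss_threshold, sites.reference_species, scheme)


# ---------------------------------------------------------------------------
# Fitch small parsimony

STATES = ("absent", "present")


@dataclass
class GainLossMap:
    tree: dendropy.Tree
    node_states: dict[int, str]  # keyed by id(node)
    events: list[tuple[str, str]]  # (edge description, "gain"|"loss")
    n_events: int

    def annotated_newick(self) -> str:
        for node in self.tree.preorder_node_iter():
            state = self.node_states[id(node)]
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label}"
            node.annotations.drop()
            node.annotations.add_new("state", state)
        return self.tree.as_string(
            schema="newick", suppress_annotations=False
        ).strip()


def fitch_gain_loss(
    tree: dendropy.Tree | str,
    tip_states: Mapping[str, str],
) -> GainLossMap:
    """Minimum gain/loss history of a binary presence character on a tree.

    Implemented as unweighted Sankoff parsimony (exact on polytomies).
    Ambiguous internal nodes are resolved preorder, preferring the parent's
    state; the root prefers ``present`` on a tie.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = tree.clone(depth=1)
    cost: dict[int, tuple[float, float]] = {}  # (cost if absent, cost if present)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in tip_states:
                raise ValueError(f"tip {label!r} has no state")
            st = tip_states[label]
            if st not in STATES:
                raise ValueError(f"bad state {st!r} for tip {label!r}")
            cost[id(node)] = (
                0.0 if st == "absent" else math.inf,
                0.0 if st == "present" else math.inf,
            )
        else:
            tot = [0.0, 0.0]
            for child in node.child_nodes():
                ca, cp = cost[id(child)]
                tot[0] += min(ca, cp + 1.0)
                tot[1] += min(cp, ca + 1.0)
            cost[id(node)] = (tot[0], tot[1])
    root = tree.seed_node
    ra, rp = cost[id(root)]
    n_events = int(min(ra, rp))
    states: dict[int, str] = {}
    events: list[tuple[str, str]] = []

    def resolve(node, parent_state: str | None) -> None:
        ca, cp = cost[id(node)]
        if parent_state is None:
            state = "present" if rp <= ra else "absent"
        else:
            # cost of choosing each state given the parent's fixed state
            choose_a = ca + (0.0 if parent_state == "absent" else 1.0)
            choose_p = cp + (0.0 if parent_state == "present" else 1.0)
            if choose_a < choose_p:
                state = "absent"
            elif choose_p < choose_a:
                state = "present"
            else:
                state = parent_state
        states[id(node)] = state
        if parent_state is not None and state != parent_state:
            label = _node_label(node)
            events.append(
                (label, "gain" if state == "present" else "loss")
            )
        for child in node.child_nodes():
            resolve(child, state)

    resolve(root, None)
    assert len(events) == n_events, "labeling does not achieve the Fitch minimum"
    return GainLossMap(tree, states, events, n_events)


def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label if node.taxon else str(node.label)
    tips = sorted(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
    )
    return "mrca(" + ",".join(tips) + ")"
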