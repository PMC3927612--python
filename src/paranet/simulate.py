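"""Forward simulator of multidomain protein family evolution.

Generates proteomes with known ortholog/paralog/epaktolog structure on a
fixed ultrametric (ladder) species tree.  Gene lineages experience six kinds
of discrete events -- gene duplication, terminal domain gain, internal domain
gain, domain loss, tandem domain duplication, and shuffling insertion (the
independent import of the same mobile domain family into unrelated
lineages, the process that creates epaktologs).  Sequences evolve by i.i.d.
substitutions along branches; there are no indels, so domain coordinates
stay exact.

The discrete events are recorded in a replayable log: re-applying the log to
the ancestral state (``replay_log``) reproduces every protein byte for byte,
because branch/instance-keyed RNG streams make the substitution process a
deterministic function of the event history and the seed.

Pair labels (ORTHOLOG / PARALOG / EPAKTOLOG / UNRELATED) are computed from
the event history, never from the sequences.  Two proteins are epaktologs
iff they descend from duplication-unconnected root genes and share a mobile
domain family acquired through *independent* shuffling-insertion events;
sharing a family through common ancestry never counts.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

ORTHOLOG = "ORTHOLOG"
PARALOG = "PARALOG"
EPAKTOLOG = "EPAKTOLOG"
UNRELATED = "UNRELATED"

GENE_DUPLICATION = "gene_duplication"
DOMAIN_GAIN_TERMINAL = "domain_gain_terminal"
DOMAIN_GAIN_INTERNAL = "domain_gain_internal"
DOMAIN_LOSS = "domain_loss"
TANDEM_DUPLICATION = "tandem_duplication"
SHUFFLING_INSERTION = "shuffling_insertion"

EVENT_KINDS = (
    GENE_DUPLICATION,
    DOMAIN_GAIN_TERMINAL,
    DOMAIN_GAIN_INTERNAL,
    DOMAIN_LOSS,
    TANDEM_DUPLICATION,
    SHUFFLING_INSERTION,
)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ConfigurationError(ValueError):
    """Raised when an EvolutionConfig cannot describe a valid simulation."""


@dataclass(frozen=True)
class DomainFamilySpec:
    """A domain family: an accession-like id, a length and a template.

    ``mobile`` marks families that participate in shuffling insertions
    (the promiscuous, typically small domains that mediate epaktology).
    """

    family_id: str
    length_aa: int
    mobile: bool
    template_sequence: str

    def __post_init__(self) -> None:
        if self.length_aa < 10:
            raise ConfigurationError(
                f"domain family {self.family_id!r}: length_aa must be >= 10"
            )
        if len(self.template_sequence) != self.length_aa:
            raise ConfigurationError(
                f"domain family {self.family_id!r}: template length mismatch"
            )


@dataclass(frozen=True)
class SimEvent:
    """One discrete event of the simulation history.

    ``branch`` is the tuple of species ids reachable from the species-tree
    branch on which the event occurred; together with ``lineage_id`` it makes
    the log replayable after speciations (the same gene lineage evolves
    independently on parallel branches).
    """

    time_my: float
    kind: str
    lineage_id: int
    branch: tuple[str, ...]
    position: int = 0
    family_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "time_my": self.time_my,
            "kind": self.kind,
            "lineage_id": self.lineage_id,
            "branch": list(self.branch),
            "position": self.position,
            "family_id": self.family_id,
        }


@dataclass
class DomainInstance:
    instance_id: int
    family_id: str
    sequence: np.ndarray  # uint8 indices into AMINO_ACIDS
    shuffling_event: int | None = None  # log index of the insertion event

    def copy_with_id(self, instance_id: int) -> "DomainInstance":
        return DomainInstance(
            instance_id=instance_id,
            family_id=self.family_id,
            sequence=self.sequence.copy(),
            shuffling_event=self.shuffling_event,
        )


@dataclass
class SimProtein:
    """An extant protein emitted by the simulator."""

    protein_id: str
    species_id: str
    lineage_id: int
    root_gene_id: int
    architecture: list[tuple[str, int]]
    sequence: str
    instances: list[DomainInstance]
    shuffled_families: dict[str, frozenset[int]]


@dataclass(frozen=True)
class GroundTruthLabel:
    protein_id_a: str
    protein_id_b: str
    relation: str


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the forward simulation.

    Event rates are per gene copy per million years; the species tree is a
    ladder (caterpillar) whose split times are given oldest-first, with
    species ``sp{i+1}`` diverging from the focal lineage (``sp0``) at
    ``species_divergence_times_my[i]``.
    """

    n_ancestral_families: int = 3
    n_mobile_families: int = 0
    n_ancestral_genes: int | None = None  # default: one gene per family
    domains_per_ancestor: tuple[int, int] = (1, 1)
    ordinary_length_range: tuple[int, int] = (60, 120)
    mobile_length_range: tuple[int, int] = (40, 70)
    n_species: int = 1
    species_divergence_times_my: tuple[float, ...] = ()
    root_age_my: float = 1000.0
    gene_duplication: float = 0.0
    domain_gain_terminal: float = 0.0
    domain_gain_internal: float = 0.0
    domain_loss: float = 0.0
    tandem_duplication: float = 0.0
    shuffling_insertion: float = 0.0
    substitution_rate: float = 2e-4  # substitutions per site per My
    linker_length_aa: int = 10
    seed: int = 0
    # scripted mode: explicit family plan / ancestral architectures / events
    family_plan: tuple[tuple[str, int, bool], ...] | None = None
    ancestral_architectures: tuple[tuple[str, ...], ...] | None = None
    scripted_events: tuple[SimEvent, ...] | None = None
    protein_aliases: tuple[tuple[tuple[int, str], str], ...] = ()

    def rates(self) -> dict[str, float]:
        return {
            GENE_DUPLICATION: self.gene_duplication,
            DOMAIN_GAIN_TERMINAL: self.domain_gain_terminal,
            DOMAIN_GAIN_INTERNAL: self.domain_gain_internal,
            DOMAIN_LOSS: self.domain_loss,
            TANDEM_DUPLICATION: self.tandem_duplication,
            SHUFFLING_INSERTION: self.shuffling_insertion,
        }

    def species_ids(self) -> tuple[str, ...]:
        return tuple(f"sp{i}" for i in range(self.n_species))

    def alias_map(self) -> dict[tuple[int, str], str]:
        return dict(self.protein_aliases)

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.family_plan is None and self.n_ancestral_families < 1:
            raise ConfigurationError("need at least one domain family")
        if self.family_plan is not None and not self.family_plan:
            raise ConfigurationError("empty family plan")
        if (
            self.ancestral_architectures is not None
            and not self.ancestral_architectures
        ):
            raise ConfigurationError("need at least one ancestral gene")
        if self.n_ancestral_genes is not None and self.n_ancestral_genes < 1:
            raise ConfigurationError("need at least one ancestral gene")
        times = self.species_divergence_times_my
        if len(times) != self.n_species - 1:
            raise ConfigurationError(
                "species_divergence_times_my must have n_species - 1 entries"
            )
        if any(t <= 0 or t >= self.root_age_my for t in times):
            raise ConfigurationError("split times must lie inside (0, root_age)")
        for older, younger in zip(times, times[1:]):
            if younger >= older:
                raise ConfigurationError(
                    "split times must strictly decrease (oldest first)"
                )
        for kind, rate in self.rates().items():
            if rate < 0 or not math.isfinite(rate):
                raise ConfigurationError(f"rate {kind} must be finite and >= 0")
        if self.substitution_rate < 0:
            raise ConfigurationError("substitution_rate must be >= 0")
        if self.linker_length_aa < 0:
            raise ConfigurationError("linker_length_aa must be >= 0")


@dataclass
class GeneCopy:
    lineage_id: int
    root_gene_id: int
    instances: list[DomainInstance]


@dataclass
class SimulationResult:
    proteins: list[SimProtein]
    labels: list[GroundTruthLabel]
    log: list[SimEvent]
    families: dict[str, DomainFamilySpec]
    config: EvolutionConfig


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, len(AMINO_ACIDS), size=length).astype(np.uint8)


def _decode(seq: np.ndarray) -> str:
    return _AA_ARRAY[seq].tobytes().decode()


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) != len(b):
        raise ValueError("instances of one family must have equal length")
    return float(np.mean(a == b))


class _Engine:
    """Applies the event process branch by branch over the ladder tree."""

    def __init__(self, config: EvolutionConfig):
        config.validate()
        self.config = config
        self.rng_setup = np.random.default_rng([config.seed % (2**31), 11])
        self.rng_events = np.random.default_rng([config.seed % (2**31), 13])
        self.families: dict[str, DomainFamilySpec] = {}
        self.log: list[SimEvent] = []
        self.proteins: list[SimProtein] = []
        self._next_lineage = 0
        self._next_instance = 0
        self._next_branch = 0
        self._build_families()

    # -- setup ---------------------------------------------------------

    def _build_families(self) -> None:
        cfg = self.config
        if cfg.family_plan is not None:
            plan = list(cfg.family_plan)
        else:
            plan = []
            n_ord = cfg.n_ancestral_families - cfg.n_mobile_families
            if n_ord < 1:
                raise ConfigurationError(
                    "need at least one non-mobile ancestral family"
                )
            lo, hi = cfg.ordinary_length_range
            for i in range(n_ord):
                plan.append(
                    (f"D{i:03d}", int(self.rng_setup.integers(lo, hi + 1)), False)
                )
            lo, hi = cfg.mobile_length_range
            for i in range(cfg.n_mobile_families):
                plan.append(
                    (f"S{i:03d}", int(self.rng_setup.integers(lo, hi + 1)), True)
                )
        for family_id, length, mobile in plan:
            if family_id in self.families:
                raise ConfigurationError(f"duplicate family id {family_id!r}")
            self.families[family_id] = DomainFamilySpec(
                family_id=family_id,
                length_aa=length,
                mobile=mobile,
                template_sequence=_decode(_random_sequence(self.rng_setup, length)),
            )

    def _template_indices(self, family_id: str) -> np.ndarray:
        spec = self.families[family_id]
        raw = np.frombuffer(spec.template_sequence.encode(), dtype=np.uint8)
        # map ASCII back to alphabet indices
        lookup = np.zeros(256, dtype=np.uint8)
        lookup[_AA_ARRAY] = np.arange(len(AMINO_ACIDS), dtype=np.uint8)
        return lookup[raw]

    def _fresh_instance(
        self, family_id: str, shuffling_event: int | None = None
    ) -> DomainInstance:
        inst = DomainInstance(
            instance_id=self._next_instance,
            family_id=family_id,
            sequence=self._template_indices(family_id),
            shuffling_event=shuffling_event,
        )
        self._next_instance += 1
        return inst

    def _ancestral_genes(self) -> dict[int, GeneCopy]:
        cfg = self.config
        if cfg.ancestral_architectures is not None:
            archs = [tuple(a) for a in cfg.ancestral_architectures]
        else:
            n_genes = (
                cfg.n_ancestral_genes
                if cfg.n_ancestral_genes is not None
                else cfg.n_ancestral_families - cfg.n_mobile_families
            )
            if n_genes < 1:
                raise ConfigurationError("need at least one ancestral gene")
            ordinary = [f for f in self.families.values() if not f.mobile]
            lo, hi = cfg.domains_per_ancestor
            counts = self.rng_setup.integers(lo, hi + 1, size=n_genes)
            if counts.sum() > len(ordinary):
                raise ConfigurationError(
                    "not enough non-mobile families for disjoint ancestral "
                    f"architectures ({counts.sum()} needed, {len(ordinary)} available)"
                )
            pool = list(self.rng_setup.permutation([f.family_id for f in ordinary]))
            archs = []
            for c in counts:
                archs.append(tuple(pool.pop() for _ in range(int(c))))
        genes: dict[int, GeneCopy] = {}
        for arch in archs:
            for fam in arch:
                if fam not in self.families:
                    raise ConfigurationError(f"unknown family {fam!r} in architecture")
            lineage = self._next_lineage
            self._next_lineage += 1
            genes[lineage] = GeneCopy(
                lineage_id=lineage,
                root_gene_id=lineage,
                instances=[self._fresh_instance(fam) for fam in arch],
            )
        return genes

    # -- evolution -----------------------------------------------------

    def run(self, scripted: Sequence[SimEvent] | None) -> None:
        cfg = self.config
        genes = self._ancestral_genes()
        species = list(cfg.species_ids())
        pending = list(zip(cfg.species_divergence_times_my, species[1:]))
        self._run_branch(genes, cfg.root_age_my, tuple(species), pending, scripted)
        self.proteins.sort(key=lambda p: (p.species_id, p.lineage_id))

    def _run_branch(
        self,
        genes: dict[int, GeneCopy],
        t_start: float,
        branch_species: tuple[str, ...],
        pending: list[tuple[float, str]],
        scripted: Sequence[SimEvent] | None,
    ) -> None:
        branch_id = self._next_branch
        self._next_branch += 1
        t_end = pending[0][0] if pending else 0.0
        self._evolve_segment(genes, t_start, t_end, branch_species, branch_id, scripted)
        if pending:
            split_time, diverging = pending[0]
            side = {
                lin: GeneCopy(
                    lineage_id=g.lineage_id,
                    root_gene_id=g.root_gene_id,
                    instances=[i.copy_with_id(i.instance_id) for i in g.instances],
                )
                for lin, g in genes.items()
            }
            self._run_branch(side, split_time, (diverging,), [], scripted)
            remaining = tuple(s for s in branch_species if s != diverging)
            self._run_branch(genes, split_time, remaining, pending[1:], scripted)
        else:
            (species_id,) = branch_species
            self._emit(genes, species_id)

    def _evolve_segment(
        self,
        genes: dict[int, GeneCopy],
        t_start: float,
        t_end: float,
        branch_species: tuple[str, ...],
        branch_id: int,
        scripted: Sequence[SimEvent] | None,
    ) -> None:
        cfg = self.config
        rng_mut = np.random.default_rng([cfg.seed % (2**31), 17, branch_id])
        if scripted is not None:
            events = [
                e
                for e in scripted
                if tuple(e.branch) == branch_species and t_end < e.time_my <= t_start
            ]
            events.sort(key=lambda e: -e.time_my)
        else:
            events = self._sample_events(genes, t_start, t_end, branch_species)
        cursor = t_start
        for event in events:
            if not self._event_applicable(genes, event):
                continue  # no log entry, no effect on mutation segmentation
            self._mutate_all(genes, cursor - event.time_my, rng_mut)
            self._apply_event(genes, event)
            cursor = event.time_my
        self._mutate_all(genes, cursor - t_end, rng_mut)

    def _sample_events(
        self,
        genes: dict[int, GeneCopy],
        t_start: float,
        t_end: float,
        branch_species: tuple[str, ...],
    ) -> list[SimEvent]:
        duration = t_start - t_end
        rates = self.config.rates()
        drafts: list[SimEvent] = []
        for lineage in sorted(genes):
            for kind in EVENT_KINDS:
                rate = rates[kind]
                if rate <= 0:
                    continue
                n = int(self.rng_events.poisson(rate * duration))
                for _ in range(n):
                    t = float(self.rng_events.uniform(t_end, t_start))
                    drafts.append(
                        SimEvent(
                            time_my=t,
                            kind=kind,
                            lineage_id=lineage,
                            branch=branch_species,
                            position=-1,
                            family_id=None,
                        )
                    )
        drafts.sort(key=lambda e: -e.time_my)
        return drafts

    def _event_applicable(self, genes: dict[int, GeneCopy], event: SimEvent) -> bool:
        """Whether the event can take effect at all.

        Events that cannot (loss or internal gain on a one-domain gene,
        shuffling with no mobile family) are dropped before they touch the
        mutation-segmentation clock, so the recorded log replays exactly.
        """
        gene = genes.get(event.lineage_id)
        if gene is None:
            raise ConfigurationError(
                f"event at {event.time_my} My names lineage {event.lineage_id}, "
                "which is absent on its branch"
            )
        n = len(gene.instances)
        if event.kind in (DOMAIN_LOSS, DOMAIN_GAIN_INTERNAL) and n < 2:
            return False
        if event.kind == SHUFFLING_INSERTION and event.family_id is None:
            if not any(f.mobile for f in self.families.values()):
                return False
        return True

    def _apply_event(self, genes: dict[int, GeneCopy], event: SimEvent) -> None:
        gene = genes.get(event.lineage_id)
        if gene is None:
            raise ConfigurationError(
                f"event at {event.time_my} My names lineage {event.lineage_id}, "
                "which is absent on its branch"
            )
        rng = self.rng_events
        n = len(gene.instances)
        kind = event.kind
        resolved = event
        if kind == GENE_DUPLICATION:
            new_lineage = self._next_lineage
            self._next_lineage += 1
            child = GeneCopy(
                lineage_id=new_lineage,
                root_gene_id=gene.root_gene_id,
                instances=[],
            )
            for inst in gene.instances:
                child.instances.append(inst.copy_with_id(self._next_instance))
                self._next_instance += 1
            genes[new_lineage] = child
            resolved = replace(event, position=0, family_id=None)
        elif kind == DOMAIN_GAIN_TERMINAL:
            pos = event.position
            fam = event.family_id
            if pos < 0:
                pos = 0 if rng.random() < 0.5 else n
            if fam is None:
                ordinary = sorted(
                    f.family_id for f in self.families.values() if not f.mobile
                )
                fam = ordinary[int(rng.integers(len(ordinary)))]
            if pos not in (0, len(gene.instances)):
                raise ConfigurationError("terminal gain position must be an end")
            gene.instances.insert(pos, self._fresh_instance(fam))
            resolved = replace(event, position=pos, family_id=fam)
        elif kind == DOMAIN_GAIN_INTERNAL:
            if n < 2:
                return  # no internal slot; event does not happen
            pos = event.position
            fam = event.family_id
            if pos < 0:
                pos = int(rng.integers(1, n))
            if fam is None:
                ordinary = sorted(
                    f.family_id for f in self.families.values() if not f.mobile
                )
                fam = ordinary[int(rng.integers(len(ordinary)))]
            if not 1 <= pos <= n - 1:
                raise ConfigurationError("internal gain position out of range")
            gene.instances.insert(pos, self._fresh_instance(fam))
            resolved = replace(event, position=pos, family_id=fam)
        elif kind == DOMAIN_LOSS:
            if n < 2:
                return  # architectures stay non-empty
            pos = event.position
            if pos < 0:
                pos = int(rng.integers(n))
            del gene.instances[pos]
            resolved = replace(event, position=pos, family_id=None)
        elif kind == TANDEM_DUPLICATION:
            pos = event.position
            if pos < 0:
                pos = int(rng.integers(n))
            src = gene.instances[pos]
            copy = src.copy_with_id(self._next_instance)
            self._next_instance += 1
            gene.instances.insert(pos + 1, copy)
            resolved = replace(event, position=pos, family_id=src.family_id)
        elif kind == SHUFFLING_INSERTION:
            mobile = sorted(
                f.family_id for f in self.families.values() if f.mobile
            )
            fam = event.family_id
            if fam is None:
                if not mobile:
                    return
                fam = mobile[int(rng.integers(len(mobile)))]
            if not self.families[fam].mobile:
                raise ConfigurationError(
                    f"shuffling_insertion family {fam!r} is not mobile"
                )
            pos = event.position
            if pos < 0:
                pos = int(rng.integers(n + 1))
            event_id = len(self.log)
            gene.instances.insert(
                pos, self._fresh_instance(fam, shuffling_event=event_id)
            )
            resolved = replace(event, position=pos, family_id=fam)
        else:
            raise ConfigurationError(f"unknown event kind {kind!r}")
        self.log.append(resolved)

    def _mutate_all(
        self, genes: dict[int, GeneCopy], dt: float, rng: np.random.Generator
    ) -> None:
        if dt <= 0:
            return
        p = 1.0 - math.exp(-self.config.substitution_rate * dt)
        if p <= 0:
            return
        for lineage in sorted(genes):
            for inst in genes[lineage].instances:
                mask = rng.random(len(inst.sequence)) < p
                if mask.any():
                    shift = rng.integers(
                        1, len(AMINO_ACIDS), size=int(mask.sum())
                    ).astype(np.uint8)
                    seq = inst.sequence
                    seq[mask] = (seq[mask] + shift) % len(AMINO_ACIDS)

    # -- emission ------------------------------------------------------

    def _emit(self, genes: dict[int, GeneCopy], species_id: str) -> None:
        aliases = self.config.alias_map()
        linker = "G" * self.config.linker_length_aa
        for lineage in sorted(genes):
            gene = genes[lineage]
            shuffled: dict[str, set[int]] = {}
            for inst in gene.instances:
                if inst.shuffling_event is not None:
                    shuffled.setdefault(inst.family_id, set()).add(
                        inst.shuffling_event
                    )
            sequence = linker.join(_decode(i.sequence) for i in gene.instances)
            pid = aliases.get((lineage, species_id), f"L{lineage}|{species_id}")
            self.proteins.append(
                SimProtein(
                    protein_id=pid,
                    species_id=species_id,
                    lineage_id=lineage,
                    root_gene_id=gene.root_gene_id,
                    architecture=[
                        (i.family_id, i.instance_id) for i in gene.instances
                    ],
                    sequence=sequence,
                    instances=[
                        DomainInstance(
                            i.instance_id,
                            i.family_id,
                            i.sequence.copy(),
                            i.shuffling_event,
                        )
                        for i in gene.instances
                    ],
                    shuffled_families={
                        fam: frozenset(ev) for fam, ev in shuffled.items()
                    },
                )
            )


def pair_relation(a: SimProtein, b: SimProtein) -> str:
    """Relation of two proteins, derived from the recorded history."""
    if a.lineage_id == b.lineage_id:
        if a.species_id == b.species_id:
            raise ValueError("two proteins of one species share a lineage")
        return ORTHOLOG
    if a.root_gene_id == b.root_gene_id:
        return PARALOG
    for fam, events_a in a.shuffled_families.items():
        events_b = b.shuffled_families.get(fam)
        if not events_b:
            continue
        if any(ea != eb for ea in events_a for eb in events_b):
            return EPAKTOLOG
    return UNRELATED


def all_pair_labels(proteins: Sequence[SimProtein]) -> list[GroundTruthLabel]:
    labels = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            pa, pb = sorted((a.protein_id, b.protein_id))
            labels.append(GroundTruthLabel(pa, pb, pair_relation(a, b)))
    return labels


def generate_proteome(config: EvolutionConfig) -> SimulationResult:
    """Run the simulation described by ``config``.

    Returns extant proteins, all-pairs ground-truth labels and the
    replayable event log.  The output is fully determined by
    ``config.seed``.
    """
    engine = _Engine(config)
    engine.run(config.scripted_events)
    return SimulationResult(
        proteins=engine.proteins,
        labels=all_pair_labels(engine.proteins),
        log=list(engine.log),
        families=dict(engine.families),
        config=config,
    )


def replay_log(config: EvolutionConfig, log: Sequence[SimEvent]) -> list[SimProtein]:
    """Re-apply a recorded event log to the ancestral state.

    The result must equal the proteins of the run that produced the log;
    this is the generator's self-consistency contract.
    """
    engine = _Engine(config)
    engine.run(log)
    return engine.proteins


# -- emitters -----------------------------------------------------------


def emit_sequences(proteins: Sequence[SimProtein]) -> str:
    if not proteins:
        raise ValueError("no proteins to emit")
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteins
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


@dataclass(frozen=True)
class EvalueModel:
    """Monotone map from percent identity (to the family template) to a
    pseudo e-value: log10(e) = -(pident - floor) * slope, clamped.

    Instances below ``detection_floor_pct`` identity are not reported at
    all, emulating profile searches losing heavily diverged domains; the
    remaining spread puts weak hits above 1e-5 so the four-cutoff protocol
    has work to do.
    """

    detection_floor_pct: float = 35.0
    slope: float = 0.35
    e_min: float = 1e-180
    e_max: float = 10.0

    def __call__(self, pident: float) -> float | None:
        if pident < self.detection_floor_pct:
            return None
        e = 10.0 ** (-(pident - self.detection_floor_pct) * self.slope)
        return min(max(e, self.e_min), self.e_max)


def emit_domain_annotations(
    proteins: Sequence[SimProtein],
    families: Mapping[str, DomainFamilySpec],
    evalue_model: Callable[[float], float | None] | None = None,
    linker_length_aa: int = 10,
) -> pd.DataFrame:
    """Per-protein domain annotation rows (1-based inclusive coordinates)."""
    model = evalue_model if evalue_model is not None else EvalueModel()
    lookup = np.zeros(256, dtype=np.uint8)
    lookup[_AA_ARRAY] = np.arange(len(AMINO_ACIDS), dtype=np.uint8)
    rows = []
    for p in proteins:
        offset = 0
        for idx, inst in enumerate(p.instances):
            spec = families[inst.family_id]
            start = offset + 1
            end = offset + spec.length_aa
            template = lookup[
                np.frombuffer(spec.template_sequence.encode(), dtype=np.uint8)
            ]
            pident = 100.0 * _identity(inst.sequence, template)
            evalue = model(pident)
            if evalue is not None:
                rows.append(
                    {
                        "protein_id": p.protein_id,
                        "family_id": inst.family_id,
                        "start": start,
                        "end": end,
                        "evalue": evalue,
                    }
                )
            offset = end + (linker_length_aa if idx < len(p.instances) - 1 else 0)
    return pd.DataFrame(
        rows, columns=["protein_id", "family_id", "start", "end", "evalue"]
    )


@dataclass(frozen=True)
class ScorerConfig:
    """Bit-score model for the built-in all-against-all comparison.

    The score of a protein pair is the best colinear chain over pairs of
    same-family domain instances, each contributing identity x length x
    ``scale`` bits; tandem arrays of a shared mobile family therefore
    inflate the pair score roughly linearly in the number of aligned
    copies.  The pseudo e-value is 10**(-bitscore / s0), clamped.
    """

    scale: float = 2.0
    s0: float = 10.0
    e_min: float = 1e-180
    e_max: float = 10.0

    def evalue(self, bitscore: float) -> float:
        return min(max(10.0 ** (-bitscore / self.s0), self.e_min), self.e_max)


def _chain(a: SimProtein, b: SimProtein) -> tuple[float, int]:
    """Best colinear chain of same-family instance pairs.

    Returns (sum of identity*length over chained pairs, total chained
    length).  Dynamic program over the two architectures; no instance is
    used twice and matched pairs are strictly increasing in both proteins.
    """
    na, nb = len(a.instances), len(b.instances)
    score = np.zeros((na + 1, nb + 1))
    length = np.zeros((na + 1, nb + 1), dtype=int)
    for i in range(1, na + 1):
        ia = a.instances[i - 1]
        for j in range(1, nb + 1):
            ib = b.instances[j - 1]
            best, blen = score[i - 1, j], length[i - 1, j]
            if score[i, j - 1] > best:
                best, blen = score[i, j - 1], length[i, j - 1]
            if ia.family_id == ib.family_id:
                w = _identity(ia.sequence, ib.sequence) * len(ia.sequence)
                cand = score[i - 1, j - 1] + w
                if cand > best:
                    best, blen = cand, length[i - 1, j - 1] + len(ia.sequence)
            score[i, j] = best
            length[i, j] = blen
    return float(score[na, nb]), int(length[na, nb])


def score_all_pairs(
    proteins: Sequence[SimProtein],
    scorer: ScorerConfig | None = None,
) -> pd.DataFrame:
    """All-against-all similarity hits in BLAST outfmt-6 column order.

    Scores are symmetric; pairs sharing no homologous domain family produce
    no row.  Self hits are emitted (they are excluded downstream, as in a
    real BLAST workflow).  Unused tabular columns are filled with 0.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to compare")
    cfg = scorer if scorer is not None else ScorerConfig()
    rows = []
    for i, a in enumerate(proteins):
        for b in proteins[i:]:
            raw, chained_len = _chain(a, b)
            if raw <= 0 or chained_len == 0:
                continue
            bitscore = round(cfg.scale * raw, 2)
            pident = round(100.0 * raw / chained_len, 2)
            evalue = cfg.evalue(bitscore)
            rows.append((a.protein_id, b.protein_id, pident, chained_len, evalue, bitscore))
            if a.protein_id != b.protein_id:
                rows.append((b.protein_id, a.protein_id, pident, chained_len, evalue, bitscore))
    frame = pd.DataFrame(
        rows, columns=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
    )
    for col in ["mismatch", "gapopen", "qstart", "qend", "sstart", "send"]:
        frame[col] = 0
    return frame[HIT_COLUMNS].sort_values(
        ["qseqid", "bitscore"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def labels_to_frame(labels: Sequence[GroundTruthLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.protein_id_a, l.protein_id_b, l.relation) for l in labels],
        columns=["protein_id_a", "protein_id_b", "relation"],
    )


def log_to_json(log: Sequence[SimEvent]) -> str:
    return json.dumps([e.to_dict() for e in log], indent=1)


def log_from_json(text: str) -> list[SimEvent]:
    return [
        SimEvent(
            time_my=d["time_my"],
            kind=d["kind"],
            lineage_id=d["lineage_id"],
            branch=tuple(d["branch"]),
            position=d["position"],
            family_id=d["family_id"],
        )
        for d in json.loads(text)
    ]


# -- presets ------------------------------------------------------------


def _shuffle_confusion_events(
    internal: bool, n_tandem: int
) -> tuple[SimEvent, ...]:
    """Scripted history of the two-lineage shuffling scenario.

    Lineage 0 (gene A, architecture a-b) duplicates at 600 My; an s domain
    is then inserted into one copy (A1*) and tandem-duplicated.  Lineage 1
    (gene X, architecture x-z) acquires its own s insertion early, amplifies
    it, and only then duplicates twice, so the three X paralogs all carry
    the tandem array and prefer one another over the epaktolog A1*.
    ``internal`` selects between mid-architecture and terminal insertion
    sites (the two variants of the scenario).
    """
    br = ("sp0",)
    pos_a = 1 if internal else 0
    pos_x = 1 if internal else 2
    events: list[SimEvent] = [
        SimEvent(900.0, SHUFFLING_INSERTION, 1, br, pos_x, "s"),
    ]
    for i in range(n_tandem):
        events.append(
            SimEvent(890.0 - 10.0 * i, TANDEM_DUPLICATION, 1, br, pos_x, "s")
        )
    events += [
        SimEvent(600.0, GENE_DUPLICATION, 0, br),
        SimEvent(500.0, GENE_DUPLICATION, 1, br),
        SimEvent(450.0, GENE_DUPLICATION, 1, br),
        SimEvent(400.0, SHUFFLING_INSERTION, 0, br, pos_a, "s"),
    ]
    for i in range(n_tandem):
        events.append(
            SimEvent(390.0 - 10.0 * i, TANDEM_DUPLICATION, 0, br, pos_a, "s")
        )
    return tuple(events)


def shuffle_confusion_config(
    seed: int,
    internal: bool = True,
    n_tandem: int = 3,
    n_species: int = 1,
    outgroup_split_my: float = 950.0,
) -> EvolutionConfig:
    """Preset for the epaktolog-confusion scenario.

    With ``internal=True`` the mobile ``s`` domain is inserted internally
    (architectures a-s..s-b vs x-s..s-z); with ``internal=False`` it is
    inserted terminally (s..s-a-b vs x-z-s..s).  ``n_tandem`` controls the
    number of tandem duplications after each insertion.  ``n_species=2``
    adds an outgroup species that diverges before every scripted event and
    therefore retains the ancestral a-b and x-z proteins.
    """
    aliases = {
        (0, "sp0"): "A1*",
        (2, "sp0"): "A2*",
        (1, "sp0"): "X1*",
        (3, "sp0"): "X2*",
        (4, "sp0"): "X3*",
    }
    if n_species == 2:
        aliases.update({(0, "sp1"): "Aout", (1, "sp1"): "Xout"})
    return EvolutionConfig(
        family_plan=(
            ("a", 60, False),
            ("b", 60, False),
            ("x", 60, False),
            ("z", 60, False),
            ("s", 60, True),
        ),
        ancestral_architectures=(("a", "b"), ("x", "z")),
        n_species=n_species,
        species_divergence_times_my=(outgroup_split_my,) if n_species == 2 else (),
        root_age_my=1000.0,
        substitution_rate=2e-4,
        linker_length_aa=10,
        seed=seed,
        scripted_events=_shuffle_confusion_events(internal, n_tandem),
        protein_aliases=tuple(aliases.items()),
    )


def shuffle_internal_config(seed: int, n_tandem: int = 3) -> EvolutionConfig:
    """Confusion scenario with internal insertion of the mobile domain."""
    return shuffle_confusion_config(seed, internal=True, n_tandem=n_tandem)


def shuffle_terminal_config(seed: int, n_tandem: int = 3) -> EvolutionConfig:
    """Confusion scenario with terminal insertion of the mobile domain."""
    return shuffle_confusion_config(seed, internal=False, n_tandem=n_tandem)


def three_species_config(seed: int) -> EvolutionConfig:
    """Three-species ladder with one old and one recent gene duplication.

    sp1 diverges at 910 My, sp2 at 430 My.  Gene 0 duplicates at 700 My
    (after the sp1 split, before the sp2 split); gene 1 duplicates at
    150 My (focal lineage only); gene 2 never duplicates.  The oldest
    outgroup therefore clusters more focal queries than the youngest.
    """
    fams = tuple((f"f{i}", 60, False) for i in range(9))
    return EvolutionConfig(
        family_plan=fams,
        ancestral_architectures=(
            ("f0", "f1", "f2"),
            ("f3", "f4", "f5"),
            ("f6", "f7", "f8"),
        ),
        n_species=3,
        species_divergence_times_my=(910.0, 430.0),
        root_age_my=1000.0,
        substitution_rate=2e-4,
        seed=seed,
        scripted_events=(
            SimEvent(700.0, GENE_DUPLICATION, 0, ("sp0", "sp2")),
            SimEvent(150.0, GENE_DUPLICATION, 1, ("sp0",)),
        ),
    )
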