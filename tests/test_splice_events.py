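"""Event reconstruction vs an independent sequence-splicing oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from minisplice.gene_model import Domain, TranscriptModel
from minisplice.splice_events import (
    CRYPTIC_SITE_USE,
    EXON_SKIP,
    FRAMESHIFT,
    IN_FRAME_DEL,
    IN_FRAME_INS,
    INTRON_RETENTION,
    PARTIAL_EXON_DEL,
    PARTIAL_INTRON_INCLUSION,
    EventConflictError,
    MinigeneConstruct,
    SpliceEvent,
    UnknownTargetError,
    consequence_of,
    event_label,
    reconstruct_product,
)
from minisplice.synthetic_data import SimulationConfig, generate_gene


# --- independent oracle: splice literal strings, measure, translate -------


def oracle_splice(construct, events):
    """Assemble the mature product by naive string surgery."""
    by = {e.target_id: e for e in events}
    out = "N" * construct.vector_exon_5len
    n_ex = len(construct.insert_exons)
    for i, (eid, _) in enumerate(construct.insert_exons):
        seq = construct.exon_seqs[eid]
        if eid in by:
            ev = by[eid]
            if ev.kind == EXON_SKIP:
                seq = ""
            elif ev.kind == PARTIAL_EXON_DEL and ev.side == "p":
                seq = seq[ev.boundary_shift_nt :]
            elif ev.kind == PARTIAL_EXON_DEL:
                seq = seq[: -ev.boundary_shift_nt]
        out += seq
        if i < n_ex - 1:
            iid = construct.insert_introns[i][0]
            if iid in by:
                ev = by[iid]
                iseq = construct.intron_seqs[iid]
                if ev.kind == INTRON_RETENTION:
                    out += iseq
                elif ev.side == "p":
                    out += iseq[: ev.boundary_shift_nt]
                else:
                    out += iseq[-ev.boundary_shift_nt :]
    return out + "N" * construct.effective_vector_3len


def oracle_frame_and_ptc(construct, canonical_seq, variant_seq):
    """Frame consequence and first in-frame stop, by literal translation."""
    frame = (len(variant_seq) - len(canonical_seq)) % 3
    insert = variant_seq[
        construct.vector_exon_5len : len(variant_seq)
        - construct.effective_vector_3len
    ]
    trimmed = insert[: len(insert) - len(insert) % 3]
    aa = str(Seq(trimmed).translate())
    ptc = aa.index("*") + 1 if "*" in aa else None
    return frame, ptc


def random_construct(rng, with_terminal=False):
    cfg = SimulationConfig(seed=int(rng.integers(2**31)), n_exons=4)
    model, seqs = generate_gene(cfg)
    exons = tuple((f"E{i}", model.exon_lengths[i - 1]) for i in range(1, 5))
    introns = tuple(
        (f"I{i}", len(seqs.intron_seqs[f"I{i}"])) for i in range(1, 4)
    )
    return MinigeneConstruct(
        insert_exons=exons,
        insert_introns=introns,
        contains_terminal_exon=with_terminal,
        exon_seqs=seqs.exon_seqs,
        intron_seqs=seqs.intron_seqs,
    )


def random_events(rng, construct, n):
    targets = list(construct.insert_exons) + list(construct.insert_introns)
    picks = rng.choice(len(targets), size=n, replace=False)
    events = []
    for k in picks:
        tid, ln = targets[k]
        if tid.startswith("E"):
            kind = rng.choice([EXON_SKIP, PARTIAL_EXON_DEL])
        else:
            kind = rng.choice(
                [INTRON_RETENTION, PARTIAL_INTRON_INCLUSION, CRYPTIC_SITE_USE]
            )
        if kind in (EXON_SKIP, INTRON_RETENTION):
            events.append(SpliceEvent(kind, tid))
        else:
            shift = int(rng.integers(1, ln))
            side = rng.choice(["p", "q"])
            events.append(SpliceEvent(kind, tid, shift, side))
    return events


# --- unit behaviour -------------------------------------------------------


class TestReconstruction:
    def test_canonical_identity(self, rng):
        c = random_construct(rng)
        p = reconstruct_product(c, [])
        assert p.length_nt == c.canonical_length
        assert p.is_canonical and p.consequence == "canonical"

    def test_exon_skip_subtracts(self, rng):
        c = random_construct(rng)
        ln = c.element_length("E2")
        p = reconstruct_product(c, [SpliceEvent(EXON_SKIP, "E2")])
        assert p.length_nt == c.canonical_length - ln

    def test_intron_retention_83nt_frameshifts(self):
        # an 83-nt retained intron shifts the frame (83 mod 3 = 2)
        c = MinigeneConstruct(
            insert_exons=(("E1", 90), ("E2", 60)),
            insert_introns=(("I1", 83),),
        )
        p = reconstruct_product(c, [SpliceEvent(INTRON_RETENTION, "I1")])
        assert p.length_nt == c.canonical_length + 83
        assert p.consequence == FRAMESHIFT

    def test_conflicting_events_rejected(self, rng):
        c = random_construct(rng)
        with pytest.raises(EventConflictError):
            reconstruct_product(
                c,
                [SpliceEvent(EXON_SKIP, "E2"), SpliceEvent(PARTIAL_EXON_DEL, "E2", 5, "q")],
            )

    def test_unknown_target_rejected(self, rng):
        c = random_construct(rng)
        with pytest.raises(UnknownTargetError):
            reconstruct_product(c, [SpliceEvent(EXON_SKIP, "E99")])

    def test_terminal_exon_drops_3prime_vector(self, rng):
        c = random_construct(rng, with_terminal=True)
        assert c.effective_vector_3len == 0
        assert reconstruct_product(c, []).length_nt == c.canonical_length

    def test_retained_intron_stop_found_by_translation(self):
        # intron carries an in-frame TAA: in-frame inclusion gains a PTC
        e1 = "ATG" + "GCA" * 29  # 90 nt, ends in frame
        e2 = "GCT" * 19 + "TAA"  # 60 nt
        i1 = "GTAAGTTAAGCA" * 2  # 24 nt, contains TAA in frame after e1
        c = MinigeneConstruct(
            insert_exons=(("E1", 90), ("E2", 60)),
            insert_introns=(("I1", 24),),
            exon_seqs={"E1": e1, "E2": e2},
            intron_seqs={"I1": i1},
        )
        p = reconstruct_product(c, [SpliceEvent(INTRON_RETENTION, "I1")])
        assert p.consequence == IN_FRAME_INS
        canonical = oracle_splice(c, [])
        _, ptc = oracle_frame_and_ptc(c, canonical, oracle_splice(c, [SpliceEvent(INTRON_RETENTION, "I1")]))
        assert p.ptc_codon == ptc is not None


class TestLabels:
    @pytest.mark.parametrize(
        "event, label",
        [
            (SpliceEvent(EXON_SKIP, "E6"), "ΔE6"),
            (SpliceEvent(INTRON_RETENTION, "I6"), "▼I6"),
            (SpliceEvent(PARTIAL_EXON_DEL, "E7", 15, "q"), "ΔE7q15"),
            (SpliceEvent(PARTIAL_INTRON_INCLUSION, "I3", 20, "p"), "▼I3p20"),
            (SpliceEvent(CRYPTIC_SITE_USE, "I3", 17, "p"), "▼I3p17"),
        ],
    )
    def test_nomenclature(self, event, label):
        assert event_label(event) == label

    def test_labels_injective_over_construct_events(self, rng):
        c = random_construct(rng)
        events = [SpliceEvent(EXON_SKIP, f"E{i}") for i in range(1, 5)]
        events += [SpliceEvent(INTRON_RETENTION, f"I{i}") for i in range(1, 4)]
        events += [
            SpliceEvent(PARTIAL_EXON_DEL, "E1", k, s)
            for k in (1, 5, 9)
            for s in ("p", "q")
        ]
        labels = [event_label(e) for e in events]
        assert len(labels) == len(set(labels))


class TestFrameLaw:
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_frameshift_iff_mod3(self, seed, n_events):
        rng = np.random.default_rng(seed)
        c = random_construct(rng)
        events = random_events(rng, c, n_events)
        p = reconstruct_product(c, events)
        assert (p.consequence == FRAMESHIFT) == (p.net_cds_change_nt % 3 != 0)

    @given(st.integers(0, 2**31 - 1))
    def test_length_conservation_vs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = random_construct(rng)
        events = random_events(rng, c, int(rng.integers(1, 5)))
        p = reconstruct_product(c, events)
        assert p.length_nt == len(oracle_splice(c, events))


class TestConsequence:
    @pytest.fixture
    def model(self):
        # exon 2 (codons 31..60) inside critical domain D
        return TranscriptModel(
            "T",
            "+",
            ((0, 90), (300, 390), (700, 790)),
            1,
            270,
            domains=(Domain("D", 25, 70, critical=True),),
        )

    def test_in_frame_skip_hits_domain(self, model):
        c = MinigeneConstruct(
            insert_exons=(("E1", 90), ("E2", 90), ("E3", 90)),
            insert_introns=(("I1", 210), ("I2", 310)),
        )
        p = reconstruct_product(c, [SpliceEvent(EXON_SKIP, "E2")])
        cons = consequence_of(p, model)
        assert cons.consequence == IN_FRAME_DEL
        assert cons.affected_domains == ("D",)
        assert cons.hits_critical_domain

    def test_frameshift_extends_to_protein_end(self, model):
        c = MinigeneConstruct(
            insert_exons=(("E1", 90), ("E2", 90), ("E3", 90)),
            insert_introns=(("I1", 210), ("I2", 310)),
        )
        p = reconstruct_product(c, [SpliceEvent(INTRON_RETENTION, "I2")])
        assert p.consequence == FRAMESHIFT  # 310 mod 3 = 1
        cons = consequence_of(p, model)
        assert cons.consequence == FRAMESHIFT
        assert "D" in cons.affected_domains
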