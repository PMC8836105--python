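import pytest

from ppzlink.conservation import AlignedGroupSet
from ppzlink.seq_io import GroupLabel, SeqRecord


def make_alignment(pp1_seqs, ppz_seqs, clades_pp1=None, clades_ppz=None):
    """Build an AlignedGroupSet from raw aligned strings."""
    records = []
    labels = {}
    for i, seq in enumerate(pp1_seqs):
        sid = f"pp1_{i}"
        records.append(SeqRecord(id=sid, residues=seq))
        clade = clades_pp1[i] if clades_pp1 else "CladeX"
        labels[sid] = GroupLabel(group="PP1", clade=clade)
    for i, seq in enumerate(ppz_seqs):
        sid = f"ppz_{i}"
        records.append(SeqRecord(id=sid, residues=seq))
        clade = clades_ppz[i] if clades_ppz else "CladeX"
        labels[sid] = GroupLabel(group="PPZ", clade=clade)
    return AlignedGroupSet(records=records, labels=labels)


@pytest.fixture
def simple_alignment():
    # col:      123456
    # PP1 all:  KGLADE
    # PPZ:      DGLAD[E/D/N]
    return make_alignment(
        ["KGLADE", "KGLADE", "KGLADE"],
        ["DGLADE", "DGLADD", "DGLADN"],
    )
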