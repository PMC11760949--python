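import numpy as np
import pytest

from tet6ma.models import SingleMolecule

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_molecule(watson=(), crick=(), molecule_id="m0", chrom="chr1",
                   start=None, end=None, passes=30):
    """Assemble a SingleMolecule from (position, base, ipd) record tuples."""

    def unpack(recs):
        recs = sorted(recs)
        pos = np.array([r[0] for r in recs], dtype=np.int64)
        base = np.array([_CODE[r[1]] for r in recs], dtype=np.uint8)
        ipd = np.array([r[2] for r in recs], dtype=float)
        return pos, base, ipd

    wp, wb, wi = unpack(watson)
    cp, cb, ci = unpack(crick)
    all_pos = np.concatenate([wp, cp]) if len(wp) + len(cp) else np.array([0])
    start = int(all_pos.min()) if start is None else start
    end = int(all_pos.max()) + 1 if end is None else end
    return SingleMolecule(molecule_id, chrom, start, end, passes,
                          wp, wb, wi, cp, cb, ci)


@pytest.fixture(scope="session")
def small_genome():
    from tet6ma import make_genome

    return make_genome(1, n_chrom=1, chrom_len=10_000, n_genes=4, apt_density=120)
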