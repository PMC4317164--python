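import numpy as np
import pytest

from microx._seq import random_seq, revcomp
from microx.genome import Gene, GenomeModel, Transcript
from microx.simulate import MicroExonSpec, SimConfig, make_genome, simulate_reads


@pytest.fixture(scope="session")
def tiny_model() -> GenomeModel:
    """Two three-exon genes on opposite strands with canonical splice context.

    Gene A (+): exons (100,150), (200,224), (300,400); the 24-nt internal
    exon has AG upstream and GT downstream in sense orientation.
    Gene B (-): exons (500,600), (650,674), (720,820); sense context planted
    as genomic complements (AC left of the exon, CT right of it).
    """
    rng = np.random.default_rng(1234)
    seq = list(random_seq(rng, 1000))
    # gene A (+): canonical context for all introns
    seq[150:152] = "GT"  # donor of exon1
    seq[198:200] = "AG"  # acceptor of internal exon
    seq[224:226] = "GT"  # donor of internal exon
    seq[298:300] = "AG"  # acceptor of exon3
    # gene B (-): sense donor/acceptor are genomic revcomps
    seq[718:720] = "CT"  # sense donor of exon at (720,820) side... (acceptor of internal's upstream)
    seq[674:676] = "CT"  # sense acceptor context of internal exon (revcomp -> AG)
    seq[648:650] = "AC"  # sense donor context of internal exon (revcomp -> GT)
    seq[598:600] = "AC"
    contig = "".join(seq)
    tA = Transcript("tA", "gA", "chrT", "+", [(100, 150), (200, 224), (300, 400)])
    tB = Transcript("tB", "gB", "chrT", "-", [(500, 600), (650, 674), (720, 820)])
    return GenomeModel(
        contigs={"chrT": contig},
        genes=[
            Gene("gA", "chrT", "+", [tA]),
            Gene("gB", "chrT", "-", [tB]),
        ],
        source="fixture",
    )


@pytest.fixture(scope="session")
def sim_default():
    """Default simulated study: 12 genes (CS/AS/BS mix), 8 samples, 3 tissues."""
    config = SimConfig()
    sim = make_genome(config, seed=11)
    reads = simulate_reads(sim, seed=12)
    return sim, reads


@pytest.fixture(scope="session")
def sim_novel():
    """Eight genes whose micro-exons are withheld from the annotation."""
    config = SimConfig(
        n_genes=8,
        plan=tuple(
            MicroExonSpec(
                length=6 + 3 * (i % 6),
                kind="AS",
                novel=True,
                psi={s: 40.0 for s in SimConfig().samples},
            )
            for i in range(8)
        ),
    )
    sim = make_genome(config, seed=21)
    reads = simulate_reads(sim, seed=22)
    return sim, reads


@pytest.fixture()
def sam_files(tmp_path):
    """Materialize per-sample SAM text as files; returns a writer helper."""

    def write(sam_by_sample):
        paths = {}
        for sample, text in sam_by_sample.items():
            p = tmp_path / f"{sample}.sam"
            p.write_text(text)
            paths[sample] = str(p)
        return paths

    return write
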