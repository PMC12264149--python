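import numpy as np
import pytest

from m6akit import simulate as sim
from m6akit.core import AnnotationBundle, GeneModel, TranscriptModel


def make_bundle(sequence=None, chrom_size=10_000):
    """Hand-built annotation with one plus-strand coding gene, one
    minus-strand coding gene and one non-coding gene.

    geneA (+): exons [100,300)+[400,700); 5'UTR 50 nt, CDS 300 nt,
    stop codon at [550,553), 3'UTR 147 nt.
    geneB (-): exons [2000,2200)+[2300,2600); 5'UTR 100 nt, CDS 300 nt,
    stop codon at [2097,2100), 3'UTR 97 nt.
    geneC (+): single non-coding exon [5000,5400).
    """
    tx_a = TranscriptModel(
        transcript_id="geneA.t1", gene_id="geneA", chrom="chr1", strand="+",
        exons=[(100, 300), (400, 700)],
        cds=[(150, 300), (400, 550)],
        stop_codon=(550, 553),
    )
    tx_b = TranscriptModel(
        transcript_id="geneB.t1", gene_id="geneB", chrom="chr1", strand="-",
        exons=[(2000, 2200), (2300, 2600)],
        cds=[(2100, 2200), (2300, 2500)],
        stop_codon=(2097, 2100),
    )
    tx_c = TranscriptModel(
        transcript_id="geneC.t1", gene_id="geneC", chrom="chr1", strand="+",
        exons=[(5000, 5400)],
    )
    genes = {
        "geneA": GeneModel("geneA", "chr1", "+", 100, 700),
        "geneB": GeneModel("geneB", "chr1", "-", 2000, 2600),
        "geneC": GeneModel("geneC", "chr1", "+", 5000, 5400, biotype="lncRNA"),
    }
    bundle = AnnotationBundle(genes=genes, transcripts=[tx_a, tx_b, tx_c],
                              chrom_sizes={"chr1": chrom_size}, sequence=sequence)
    bundle.validate()
    return bundle


@pytest.fixture
def toy_bundle():
    return make_bundle()


def small_sim_config(**overrides):
    defaults = dict(
        n_genes=40, n_chromosomes=2, chrom_length=300_000,
        n_mdecay=5, n_zdecay=5, n_zga=5, n_constant=8,
        loci_per_subfamily=10, n_erv_elements=8, seed=7,
    )
    defaults.update(overrides)
    return sim.SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulation: annotation + stage experiment."""
    cfg = small_sim_config()
    bundle, repeats, consensus, homology, truth = sim.simulate_annotation(cfg)
    data = sim.simulate_stage_experiment(cfg, bundle, truth, repeats)
    return {"cfg": cfg, "bundle": bundle, "repeats": repeats,
            "consensus": consensus, "homology": homology,
            "truth": truth, "data": data}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
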