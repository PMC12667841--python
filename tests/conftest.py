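import textwrap

import numpy as np
import pandas as pd
import pytest

from crypticburden.io_formats import CohortDesign, GenomicJunction, JunctionTable
from crypticburden.splicing_core import PsiMatrix


MINI_GTF = textwrap.dedent(
    """\
    chr1\ttest\tgene\t101\t600\t.\t+\t.\tgene_id "gA";
    chr1\ttest\ttranscript\t101\t600\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
    chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
    chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
    chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
    chr1\ttest\tgene\t2001\t2600\t.\t-\t.\tgene_id "gB";
    chr1\ttest\ttranscript\t2001\t2600\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
    chr1\ttest\texon\t2001\t2100\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
    chr1\ttest\texon\t2301\t2400\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
    chr1\ttest\texon\t2501\t2600\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
    chr2\ttest\tgene\t101\t400\t.\t+\t.\tgene_id "gC";
    chr2\ttest\ttranscript\t101\t400\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t1";
    chr2\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t1";
    chr2\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t1";
    chr3\ttest\tgene\t101\t900\t.\t+\t.\tgene_id "gD";
    chr3\ttest\ttranscript\t101\t900\t.\t+\t.\tgene_id "gD"; transcript_id "gD.t1";
    chr3\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gD"; transcript_id "gD.t1";
    chr3\ttest\texon\t801\t900\t.\t+\t.\tgene_id "gD"; transcript_id "gD.t1";
    chr3\ttest\tgene\t301\t700\t.\t+\t.\tgene_id "gE";
    chr3\ttest\ttranscript\t301\t700\t.\t+\t.\tgene_id "gE"; transcript_id "gE.t1";
    chr3\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gE"; transcript_id "gE.t1";
    chr3\ttest\texon\t601\t700\t.\t+\t.\tgene_id "gE"; transcript_id "gE.t1";
    """
)
# Half-open exons: gA chr1+ [100,200) [300,400) [500,600);
# gB chr1- [2000,2100) [2300,2400) [2500,2600); gC chr2+ two exons;
# gD/gE overlap on chr3 (ambig territory).


@pytest.fixture(scope="session")
def mini_gtf_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("ann") / "mini.gtf"
    p.write_text(MINI_GTF)
    return p


@pytest.fixture(scope="session")
def mini_annotation(mini_gtf_path):
    from crypticburden.io_formats import read_annotation

    return read_annotation(mini_gtf_path)


def make_psi_matrix(psi_values, sample_ids, cluster_ids=None, min_reads=15,
                    totals=None):
    """Build a PsiMatrix directly from latent PSI values (one junction per
    row; default one singleton cluster each)."""
    psi = pd.DataFrame(psi_values, columns=sample_ids)
    junctions = [
        GenomicJunction("chr1", 1000 * (i + 1), 1000 * (i + 1) + 200, "+")
        for i in range(len(psi))
    ]
    psi.index = [j.id for j in junctions]
    if cluster_ids is None:
        cluster_ids = [f"clu_{i}" for i in range(len(psi))]
    if totals is None:
        totals = pd.DataFrame(10_000, index=psi.index, columns=sample_ids)
    return PsiMatrix(psi, totals, junctions, cluster_ids, min_reads)


@pytest.fixture
def simple_table():
    """Two clusters x three samples with hand-set counts."""
    junctions = [
        GenomicJunction("chr1", 100, 300, "+"),
        GenomicJunction("chr1", 100, 1300, "+"),
        GenomicJunction("chr2", 100, 300, "+"),
    ]
    counts = np.array([[30, 0, 3], [70, 10, 0], [5, 5, 5]])
    return JunctionTable(junctions, ["c1", "c1", "c2"], counts, ["s1", "s2", "s3"])


@pytest.fixture
def case_control_design():
    return CohortDesign(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "class": ["KD", "control", "control"],
            }
        )
    )
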