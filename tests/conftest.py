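import textwrap

import pytest

from mrpipe import RunConfig, SummaryAssociation


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def write_table(tmp_path):
    """Write a whitespace-delimited summary table and return its path."""

    def _write(text, name="table.tsv"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text).strip() + "\n")
        return str(path)

    return _write


def assoc(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-10, eaf=0.3,
          n=8631, gene=None, trait="exposure"):
    """Terse SummaryAssociation factory for tests."""
    return SummaryAssociation(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=p, eaf=eaf, n=n, trait=trait, gene=gene,
    )
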