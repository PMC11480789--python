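"""Shared fixtures: a hand-written lexicon with known resolution paths and
a session-scoped synthetic world (lexicon, gene-phenotype map, cohort)."""

from __future__ import annotations

import pytest

from priobench import lexicon as lexicon_mod
from priobench import synthetic

# Hand-written fixture lexicon exercising every resolution path:
# previous symbols (DDX30 -> DHX30), aliases (ABC1 -> ABCA1), blocked error
# symbols that exist as aliases (SEPT1, MARC1), and an alias claimed by two
# approved symbols (SHARED).
FIXTURE_LEXICON_TSV = """\
symbol\talias_symbol\tprev_symbol
TP53\tP53|LFS1\t
BRCA1\tRNF53\t
BRCA2\tFACD\t
PTEN\tMMAC1\t
DHX30\t\tDDX30
ABCA1\tABC1\t
OPA1\tMGM1\t
SCN1A\t\tGEFSP2
KCNQ2\tEBN1\t
SEPTIN1\tSEPT1\tDIFF6
MTARC1\tMARC1\t
AMBIG1\tSHARED\t
AMBIG2\tSHARED\t
MECP2\t\t
CDKL5\t\t
STXBP1\t\t
ARX\t\t
FOXG1\t\t
PCDH19\t\t
TCF4\t\t
MEF2C\t\t
EGFR\t\t
KRAS\t\t
MYC\t\t
VHL\t\t
RB1\t\t
"""


@pytest.fixture(scope="session")
def fixture_lexicon(tmp_path_factory) -> lexicon_mod.GeneLexicon:
    path = tmp_path_factory.mktemp("lexicon") / "fixture_lexicon.tsv"
    path.write_text(FIXTURE_LEXICON_TSV, encoding="utf-8")
    return lexicon_mod.load_lexicon(path)


@pytest.fixture(scope="session")
def synthetic_lexicon(tmp_path_factory) -> lexicon_mod.GeneLexicon:
    """120 synthetic genes with random alias/previous forms."""
    path = tmp_path_factory.mktemp("synlex") / "lexicon.tsv"
    synthetic.generate_lexicon_table(120, seed=1, path=path)
    return lexicon_mod.load_lexicon(path)


@pytest.fixture(scope="session")
def synthetic_world(synthetic_lexicon):
    """A gene-phenotype map and a 1000-case cohort over the synthetic lexicon."""
    g2p = synthetic.generate_gene_phenotype_map(120, 6, seed=2)
    cohort = synthetic.generate_cohort(g2p, n_cases=1000, seed=3, pool_size=100)
    return synthetic_lexicon, g2p, cohort
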