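import pytest

from varburden.frequency import FrequencyConfig
from varburden.variant_io import CaseVariant, PanelEntry, ReferenceSite


@pytest.fixture
def config():
    return FrequencyConfig()


@pytest.fixture
def case_tsv(tmp_path):
    path = tmp_path / "cases.tsv"
    path.write_text(
        "# three qualifying case variants\n"
        "disease\tgene\tvariant_id\tconsequence\tcarrier_count\tprotein_pos\treported_class\n"
        "HCM\tMYBPC3\t11:47364249:G:A\tmissense_variant\t104\t502\tP\n"
        "HCM\tMYBPC3\t11:47356597:C:T\tstop_gained\t6\t1096\tLP\n"
        "HCM\tMYH7\t14:23894573:C:T\tmissense_variant\t12\t403\tVUS\n"
    )
    return path


@pytest.fixture
def panel_tsv(tmp_path):
    path = tmp_path / "panel.tsv"
    path.write_text(
        "disease\tgene\tn_cases\tprotein_length\ttranscript_id\n"
        "HCM\tMYBPC3\t6179\t1274\tENST00000545968\n"
        "HCM\tMYH7\t6179\t1935\tENST00000355349\n"
    )
    return path


@pytest.fixture
def reference_tsv(tmp_path):
    path = tmp_path / "reference.tsv"
    path.write_text(
        "gene\tvariant_id\tconsequence\tac\tan\tprotein_pos\n"
        "MYBPC3\t11:47364249:G:A\tmissense_variant\t3\t121412\t502\n"
        "MYBPC3\t11:47359000:A:G\tmissense_variant\t80\t120000\t900\n"
        "MYH7\t14:23894573:C:T\tmissense_variant\t1\t118000\t403\n"
        "MYH7\t14:23900000:G:A\tsynonymous_variant\t5\t118000\t\n"
    )
    return path


@pytest.fixture
def small_cases():
    return [
        CaseVariant("HCM", "MYBPC3", "v1", "missense_variant", 104, 502),
        CaseVariant("HCM", "MYBPC3", "v2", "stop_gained", 6, 1096),
        CaseVariant("HCM", "MYH7", "v3", "missense_variant", 12, 403),
    ]


@pytest.fixture
def small_reference():
    return [
        ReferenceSite("MYBPC3", "v1", "missense_variant", 3, 121412, 502),
        ReferenceSite("MYBPC3", "v4", "missense_variant", 2, 120000, 900),
        ReferenceSite("MYH7", "v5", "missense_variant", 1, 118000, 120),
    ]


@pytest.fixture
def small_panel():
    return [
        PanelEntry("HCM", "MYBPC3", 6179, 1274),
        PanelEntry("HCM", "MYH7", 6179, 1935),
    ]
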