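import pytest

from adrfilter.lexicon import DrugEntry, LexiconEntry, build_index


@pytest.fixture(scope="session")
def disorder_entries():
    return [
        LexiconEntry("mal de tete", "L006", "mal de tete", "P005", "headache", "nervous system disorders"),
        LexiconEntry("mal au crane", "L013", "mal au crane", "P005", "headache", "nervous system disorders"),
        LexiconEntry("headache", "L005", "headache", "P005", "headache", "nervous system disorders"),
        LexiconEntry("insomnie", "L001", "insomnie", "P001", "insomnia", "psychiatric disorders"),
        LexiconEntry("eruption cutanee", "L007", "eruption cutanee", "P007", "rash", "skin disorders"),
    ]


@pytest.fixture(scope="session")
def drug_entries():
    return [
        DrugEntry("zolpidem", "D001"),
        DrugEntry("teriflunomide", "D002"),
        DrugEntry("aspirin", "D003"),
    ]


@pytest.fixture(scope="session")
def disorder_index(disorder_entries):
    return build_index(disorder_entries, "exact-stemmed")


@pytest.fixture(scope="session")
def drug_index(drug_entries):
    return build_index(drug_entries, "fuzzy")


@pytest.fixture
def disorder_csv(tmp_path, disorder_entries):
    path = tmp_path / "disorders.csv"
    lines = ["surface_term,llt_id,llt_label,pt_id,pt_label,soc_label"]
    for e in disorder_entries:
        lines.append(f"{e.surface_term},{e.llt_id},{e.llt_label},{e.pt_id},{e.pt_label},{e.soc_label}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def drug_csv(tmp_path, drug_entries):
    path = tmp_path / "drugs.csv"
    lines = ["drug_name,drug_id"] + [f"{d.drug_name},{d.drug_id}" for d in drug_entries]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
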