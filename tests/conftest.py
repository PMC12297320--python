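import pytest

from lymphtrial.io import PatientRecord


@pytest.fixture
def write_tsv(tmp_path):
    """Write lines (joined by tabs) to a temp TSV and return its path."""

    def _write(name, rows):
        p = tmp_path / name
        p.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return p

    return _write


def make_records(n, n_cr=0, n_pr=0, n_sd=0, n_pd=0):
    """Clinical records with the given best-response counts; rest unassessed."""
    responses = (
        ["CR"] * n_cr + ["PR"] * n_pr + ["SD"] * n_sd + ["PD"] * n_pd
    )
    responses += [None] * (n - len(responses))
    return [
        PatientRecord(
            sample_id=f"S{i:03d}",
            age_years=60,
            disease_status="relapsed",
            ipi_risk="intermediate",
            bulky_disease=False,
            response=r,
        )
        for i, r in enumerate(responses)
    ]
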