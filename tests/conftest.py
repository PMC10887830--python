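import numpy as np
import pytest

import fhpdx

# Printed initial/end boundary angles (IA, EA) for the 24 packaged lines,
# keyed by (parameter, line colour) — the published reference values the
# packaged constants must reproduce at the span endpoints.
PRINTED_IA_EA = {
    ("CSA", "blue"): (11.0, 10.4), ("CSA", "pink"): (25.1, 26.0), ("CSA", "red"): (45.5, 44.4),
    ("CCA", "blue"): (11.9, 9.4), ("CCA", "pink"): (24.2, 26.7), ("CCA", "red"): (41.2, 50.6),
    ("T1S", "blue"): (10.0, 12.3), ("T1S", "pink"): (26.4, 23.6), ("T1S", "red"): (45.6, 43.8),
    ("CL", "blue"): (5.30, 18.3), ("CL", "pink"): (22.8, 29.5), ("CL", "red"): (43.8, 46.6),
    ("CranT", "blue"): (11.6, 9.6), ("CranT", "pink"): (27.1, 23.4), ("CranT", "red"): (49.1, 40.3),
    ("CervT", "blue"): (8.5, 13.8), ("CervT", "pink"): (26.0, 24.9), ("CervT", "red"): (41.7, 50.2),
    ("C7S", "blue"): (9.4, 12.1), ("C7S", "pink"): (26.5, 24.5), ("C7S", "red"): (43.2, 47.0),
    ("TK", "blue"): (12.1, 8.6), ("TK", "pink"): (27.9, 21.6), ("TK", "red"): (46.9, 42.0),
}


@pytest.fixture(scope="session")
def bank() -> fhpdx.ModelBank:
    return fhpdx.load_model_bank()


@pytest.fixture(scope="session")
def fixture_sheet():
    return fhpdx.load_evaluation_fixture()


@pytest.fixture(scope="session")
def fixture_results(bank, fixture_sheet):
    """Vote diagnoses recomputed for the 43 packaged evaluation FNTAs."""
    return fhpdx.diagnose_cohort(
        bank,
        fixture_sheet["fnta"].astype(float).tolist(),
        fixture_sheet["participant"].astype(str).tolist(),
    )


def horizontal_line(level_pair, fnta_cut, x_min=-10.0, x_max=10.0):
    """A flat boundary at a fixed FNTA (no radiographic influence)."""
    return fhpdx.BoundaryLine(
        k=fnta_cut, l1=0.0, l2=-1.0, x_min=x_min, x_max=x_max,
        separates=level_pair,
    )


def horizontal_model(parameter, cuts=(12.0, 25.0, 40.0)):
    return fhpdx.DiagnosticModel(
        parameter=parameter,
        lines=tuple(
            horizontal_line(pair, cut)
            for pair, cut in zip(((0, 1), (1, 2), (2, 3)), cuts)
        ),
    )


@pytest.fixture(scope="session")
def horizontal_bank():
    """All eight models flat at the screening cutoffs: voting must reduce
    to plain threshold classification away from the cutoffs."""
    return fhpdx.ModelBank(
        models={p: horizontal_model(p) for p in fhpdx.PARAMETERS}
    )


def oracle_candidates(model, fnta, nx=2001, tol=1e-9):
    """Brute-force candidate levels: sweep x over a fine grid of the common
    effective span, classify (x, fnta) against each boundary by the sign of
    k + l1*x + l2*fnta, and union the per-x level assignments. Grid points
    lying exactly on a boundary are skipped (knife-edge, no information)."""
    lo = max(l.effective_range[0] for l in model.lines)
    hi = min(l.effective_range[1] for l in model.lines)
    xs = np.linspace(lo, hi, nx)
    levels = set()
    for x in xs:
        signs = [line.k + line.l1 * x + line.l2 * fnta for line in model.lines]
        if any(abs(s) <= tol for s in signs):
            continue
        # l2 < 0: a negative sign means the point lies above the boundary
        levels.add(sum(s < 0 for s in signs))
    return frozenset(levels)
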