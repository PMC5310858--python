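import pytest

from firecal import FireHistorySite, TreeSeries


def make_series(sid, first, last, scars=(), recording=True):
    """Hand-build a series: 'U' at scar years, '|' after the first scar
    (when recording), '.' elsewhere."""
    scars = sorted(scars)
    codes = []
    for year in range(first, last + 1):
        if year in scars:
            codes.append("U")
        elif recording and scars and year > scars[0]:
            codes.append("|")
        else:
            codes.append(".")
    return TreeSeries(sid, first, last, "".join(codes))


def make_site(series, site_id="TEST", **kwargs):
    return FireHistorySite(site_id=site_id, series=list(series), **kwargs)


@pytest.fixture
def simple_site():
    """Two trees, three shared fire years plus one single-tree fire."""
    return make_site(
        [
            make_series("A", 1700, 1800, scars=[1710, 1740, 1770]),
            make_series("B", 1700, 1800, scars=[1710, 1740, 1755, 1770]),
        ]
    )
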