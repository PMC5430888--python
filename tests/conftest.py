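import pytest

from genemeta import load_il7ra


#: published per-study case/control totals for the bundled IL7RA table,
#: keyed by (study_id, snp_id) — the integrity guard for the transcription
PUBLISHED_TOTALS = {
    ("Zhang2005", "rs3194051"): (667, 558),
    ("Gregory2007", "rs3194051"): (438, 478),
    ("Lundmark2007", "rs3194051"): (1785, 2564),
    ("ODoherty1_2008", "rs3194051"): (208, 413),
    ("ODoherty2_2008", "rs3194051"): (463, 531),
    ("Akkad2009", "rs3194051"): (1279, 857),
    ("Bahlo2009", "rs3194051"): (2255, 2308),
    ("Kallio2009", "rs3194051"): (197, 433),
    ("Zhang2005", "rs987107"): (528, 563),
    ("Gregory2007", "rs987107"): (438, 479),
    ("Lundmark2007", "rs987107"): (1779, 2565),
    ("ODoherty1_2008", "rs987107"): (207, 413),
    ("ODoherty2_2008", "rs987107"): (462, 527),
    ("Jager2013", "rs987107"): (484, 311),
    ("Teutsch2003", "rs11567686"): (176, 176),
    ("Broux2010", "rs11567686"): (65, 33),
    ("Hoe2010", "rs11567686"): (810, 991),
    ("Heidari2011", "rs11567686"): (100, 100),
    ("Haj2015", "rs11567686"): (202, 244),
    ("Teutsch2003", "rs11567685"): (101, 90),
    ("Booth2005", "rs11567685"): (363, 182),
    ("Akkad2009", "rs11567685"): (1304, 889),
    ("Broux2010", "rs11567685"): (65, 33),
    ("Hoe2010", "rs11567685"): (810, 991),
    ("Heidari2011", "rs11567685"): (100, 100),
    ("Ibayyan2014", "rs11567685"): (200, 200),
    ("Haj2015", "rs11567685"): (219, 258),
}


@pytest.fixture(scope="session")
def il7ra():
    return load_il7ra()


@pytest.fixture(scope="session")
def by_snp(il7ra):
    out = {}
    for s in il7ra:
        out.setdefault(s.snp_id, []).append(s)
    return out
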