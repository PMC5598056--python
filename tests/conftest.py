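from __future__ import annotations

import pytest

from detl import GeneratorConfig, generate_extracts

# A faithful CSV transcription of the published worked-example rule that
# loads the care_site table from a claims extract joined to the provider
# roster.  Database/schema attributes are left blank, as in the original.
TABLE2_CSV = """\
Rule Order,Rule Description,Target Database,Target Schema,Target Table,Target Column,Map Type,Map Order,Source Database,Source Schema,Source Table,Source Value
1,Medical_claims to Care_site,,,Care_site,,PRIMARY,1,,,Medical_claims,"medical_claims.billing_provider_id, medical_claims.place_of_service_code, provider.provider_organization_type"
1,Medical_claims to Care_site,,,Care_site,,JOIN,2,,,provider,medical_claims.billing_provider_id = provider.provider_id
1,Medical_claims to Care_site,,,Care_site,,WHERE,3,,,,"provider.provider_organization_type in ('1', '2')"
1,Medical_claims to Care_site,,,Care_site,care_site_source_value,VALUE,4,,,,medical_claims.billing_provider_id || '-' || medical_claims.place_of_service_code || '-' || provider.provider_organization_type
1,Medical_claims to Care_site,,,Care_site,organization_source_value,VALUE,5,,,,NULL
1,Medical_claims to Care_site,,,Care_site,place_of_service_source_value,VALUE,6,,,,medical_claims.place_of_service_code
1,Medical_claims to Care_site,,,Care_site,care_site_address_1,VALUE,7,,,,provider.provider_address_first_line
1,Medical_claims to Care_site,,,Care_site,care_site_address_2,VALUE,8,,,,provider.provider_street
1,Medical_claims to Care_site,,,Care_site,care_site_city,VALUE,9,,,,provider.provider_city
1,Medical_claims to Care_site,,,Care_site,care_site_state,VALUE,10,,,,provider.provider_state
1,Medical_claims to Care_site,,,Care_site,care_site_zip,VALUE,11,,,,provider.provider_zip
1,Medical_claims to Care_site,,,Care_site,care_site_county,VALUE,12,,,,NULL
"""


@pytest.fixture(scope="session")
def table2_csv(tmp_path_factory):
    path = tmp_path_factory.mktemp("rules") / "care_site_rule.csv"
    path.write_text(TABLE2_CSV, encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def clean_extracts(tmp_path_factory):
    """Small extract set with every injection rate zero."""
    out = tmp_path_factory.mktemp("clean")
    cfg = GeneratorConfig.clean(seed=3, n_claims=60, n_providers=15, n_persons=30)
    files, ledger = generate_extracts(cfg, out)
    return files, ledger, cfg


@pytest.fixture(scope="session")
def dirty_extracts(tmp_path_factory):
    """Extract set at the default injection rates, with its ledger."""
    out = tmp_path_factory.mktemp("dirty")
    cfg = GeneratorConfig(seed=7, n_claims=150, n_providers=40, n_persons=80)
    files, ledger = generate_extracts(cfg, out)
    return files, ledger, cfg
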