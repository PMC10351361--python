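version: 1
models:
- endpoint: oral_mucositis
  family: logistic_d50k
  structures:
  - ORAL_MUCOSA
  params:
    D50: 51.0
    k: 1.0
- endpoint: xerostomia
  family: probit_geud
  structures:
  - PAROTID_CONTRA
  params:
    D50: 39.9
    m: 0.4
    n: 1.0
- endpoint: swallow_solids
  family: multivar_logistic
  structures:
  - LARYNX_SUPRAGLOTTIC
  params:
    a: 5.98
    b: 0.074
    c: -1.209
    X2: 1.0
- endpoint: swallow_liquids
  family: multivar_logistic
  structures:
  - PCM_SUPERIOR
  - LARYNX_SUPRAGLOTTIC
  params:
    a: 6.89
    b: 0.049
    c: 0.048
- endpoint: dysphagia
  family: multivar_logistic
  structures:
  - PCM_SUPERIOR
  - LARYNX_SUPRAGLOTTIC
  params:
    a: 6.09
    b: 0.057
    c: 0.037
- endpoint: aspiration
  family: probit_geud
  structures:
  - LARYNX
  params:
    D50: 46.5
    m: 0.5
    n: 1.0
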