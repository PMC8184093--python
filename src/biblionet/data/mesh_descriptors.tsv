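# Synthetic MeSH descriptor fixture: mesh_id <TAB> name
# Small excerpt-style dictionary for tests and simulations; ids follow the
# MeSH naming convention but the file is a hand-built fixture, not a MeSH export.
D000086382	COVID-19
D007251	Influenza, Human
D045169	Severe Acute Respiratory Syndrome
D018352	Coronavirus Infections
D003920	Diabetes Mellitus
D006973	Hypertension
D009765	Obesity
D001249	Asthma
D011014	Pneumonia
D009369	Neoplasms
D002318	Cardiovascular Diseases
D013927	Thrombosis
D020521	Stroke
D007674	Kidney Diseases
D012128	Respiratory Distress Syndrome
C000606551	Remdesivir
D006886	Hydroxychloroquine
D003907	Dexamethasone
D017963	Azithromycin
C502936	Tocilizumab
D061466	Lopinavir
D019438	Ritonavir
C462182	Favipiravir
D007559	Ivermectin
D007372	Interferons
D006493	Heparin
D015032	Zinc
D014807	Vitamin D
D000809	Angiotensins
D000305	Adrenal Cortex Hormones
D014612	Vaccines
D000998	Antiviral Agents
D002211	Chloroquine
D011241	Prednisolone
D008775	Methylprednisolone
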