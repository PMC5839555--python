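# Sentence templates for synthetic clinical notes.
# "background" and "confounder" sentences must never contain an enabled
# lexicon term as a whole word; "mention_*" templates carry a {term} slot.
background:
  - "Patient seen in primary care clinic for routine follow-up."
  - "Blood pressure well controlled on current regimen."
  - "Discussed diet, exercise, and medication adherence."
  - "Coronary artery disease, stable; continues aspirin and statin."
  - "No chest pain, dyspnea, or palpitations since last visit."
  - "Labs reviewed; lipid panel at goal."
  - "Influenza vaccination administered today."
  - "Reports good sleep and stable mood."
  - "Plan: return to clinic in 6 months, sooner if symptoms."
  - "Colonoscopy screening discussed and declined."
mention_affirmed:
  - "Patient reports smoking {term} daily."
  - "Uses {term} several times per week for chronic pain."
  - "Admits to occasional {term} use on weekends."
  - "Tox screen positive; {term} use discussed with patient."
  - "Long history of {term} use, ongoing."
mention_negated:
  - "Denies {term} use."
  - "No current {term} use reported."
  - "Quit {term} years ago per patient report."
  - "Patient denies any {term} or other drug use this year."
mention_historical:
  - "Remote history of {term} use in early adulthood."
  - "Past {term} use, in remission."
confounder:
  - "Chronic TMJ pain, referred to dental clinic."
  - "Discussed cannabinoid receptor research trial enrollment."
  - "TMJ splint adjusted; follow up with oral surgery."
  - "Device serial MJX2 recorded at interrogation."
  - "Reviewed cannabinoid hyperemesis literature with trainee."
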