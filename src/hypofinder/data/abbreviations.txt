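# Abbreviations protected from sentence splitting (case-insensitive,
# matched as a whole word ending in the period under test).
e.g.
i.e.
et al.
al.
fig.
figs.
tab.
vs.
cf.
ca.
approx.
resp.
etc.
no.
dr.
prof.
st.
ref.
refs.
eq.
eqs.
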