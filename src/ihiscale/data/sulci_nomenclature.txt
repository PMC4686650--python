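# Sulcus nomenclature for the morphometry association analysis:
# 45 labels per hemisphere, BrainVisa-style abbreviations.
# One label per line; lines starting with '#' are ignored.
F.C.L.p.
F.C.M.ant.
F.C.M.post.
F.Cal.
F.Coll.
F.I.P.
F.P.O.
S.C.
S.C.LPC.
S.C.sylvian.
S.Call.
S.Cu.
S.F.inf.
S.F.int.
S.F.inter.
S.F.marginal.
S.F.median.
S.F.orbitaire.
S.F.polaire.tr.
S.F.sup.
S.GSM.
S.Li.
S.O.T.lat.ant.
S.O.T.lat.med.
S.O.T.lat.post.
S.O.p.
S.Olf.
S.Or.
S.Pa.int.
S.Pa.sup.
S.Pa.t.
S.Pe.C.inf.
S.Pe.C.inter.
S.Pe.C.marginal.
S.Pe.C.median.
S.Pe.C.sup.
S.Po.C.sup.
S.R.inf.
S.Rh.
S.T.i.ant.
S.T.i.post.
S.T.pol.
S.T.s.
S.T.s.ter.asc.ant.
S.T.s.ter.asc.post.
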