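>1 GLP1 wild-type
HAEGTFTSDVSSYLEGQAAKEFIAWLVKGR
>2 GLP1 A->CHA
HAEGTFTSDVSSYLEGQ[CHA]AKEFIAWLVKGR
>3 GLP1 A->NLE
HAEGTFTSDVSSYLEGQ[NLE]AKEFIAWLVKGR
>4 GLP1 A->NAC
HAEGTFTSDVSSYLEGQ[NAC]AKEFIAWLVKGR
>5 GLP1 A->AIB
HAEGTFTSDVSSYLEGQ[AIB]AKEFIAWLVKGR
>6 GLP1 A->CIT
HAEGTFTSDVSSYLEGQ[CIT]AKEFIAWLVKGR
>7 GLP1 A->CHA R->CIT
HAEGTFTSDVSSYLEGQ[CHA]AKEFIAWLVKG[CIT]
>8 GLP1 G->AIB I->CIT
HAE[AIB]TFTSDVSSYLEGQAAKEF[CIT]AWLVKGR
>9 GLP1 D->CHA E->NAC
HAEGTFTS[CHA]VSSYLEGQAAK[NAC]FIAWLVKGR
>10 GLP1 G->NLE Q->CIT
HAE[NLE]TFTSDVSSYLEG[CIT]AAKEFIAWLVKGR
>11 18A wild-type
[ntDAC]WFKAFYDKVAEKFKEA[ctFAD]
>12 18A A->CHA
[ntDAC]WFKAFYDKV[CHA]EKFKEA[ctFAD]
>13 18A A->NLE
[ntDAC]WFKAFYDKV[NLE]EKFKEA[ctFAD]
>14 18A A->NAC
[ntDAC]WFKAFYDKV[NAC]EKFKEA[ctFAD]
>15 18A A->AIB
[ntDAC]WFKAFYDKV[AIB]EKFKEA[ctFAD]
>16 18A A->CIT
[ntDAC]WFKAFYDKV[CIT]EKFKEA[ctFAD]
>17 18A F->CHA A->CHA
[ntDAC]W[CHA]KAFYDKV[CHA]EKFKEA[ctFAD]
>18 18A A->CHA A->NLE
[ntDAC]WFK[CHA]FYDKVAEKFKE[NLE][ctFAD]
>19 18A K->AIB F->CHA
[ntDAC]WF[AIB]AFYDKVAEK[CHA]KEA[ctFAD]
>20 18A F->NAC F->NLE
[ntDAC]W[NAC]KAFYDKVAEK[NLE]KEA[ctFAD]
>21 PYY3-36 wild-type
IKPEAPREDASPEELNRYYASLRHYLNLVTRQR[ctYAD]
>22 PYY3-36 A->CHA
IKPEAPRED[CHA]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>23 PYY3-36 A->NLE
IKPEAPRED[NLE]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>24 PYY3-36 A->NAC
IKPEAPRED[NAC]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>25 PYY3-36 A->AIB
IKPEAPRED[AIB]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>26 PYY3-36 A->CIT
IKPEAPRED[CIT]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>27 PYY3-36 A->CIT L->NLE
IKPEAPRED[CIT]SPEELNRYYASLRHY[NLE]NLVTRQR[ctYAD]
>28 PYY3-36 S->NLE S->NLE
IKPEAPREDA[NLE]PEELNRYYA[NLE]LRHYLNLVTRQR[ctYAD]
>29 PYY3-36 A->AIB S->NAC
IKPE[AIB]PREDASPEELNRYYA[NAC]LRHYLNLVTRQR[ctYAD]
>30 PYY3-36 I->AIB V->AIB
[AIB]KPEAPREDASPEELNRYYASLRHYLNL[AIB]TRQR[ctYAD]
>31 PYY3-36 A->DAP
IKPEAPRED[DAP]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>32 PYY3-36 A->NAP
IKPEAPRED[NAP]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>33 PYY3-36 A->TBA
IKPEAPRED[TBA]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>34 PYY3-36 A->OPO
IKPEAPRED[OPO]SPEELNRYYASLRHYLNLVTRQR[ctYAD]
>35 PYY3-36 A->CHA Y->OPO
IKPE[CHA]PREDASPEELNRYYASLRH[OPO]LNLVTRQR[ctYAD]
>36 PYY3-36 A->OPO L->TBA
IKPE[OPO]PREDASPEELNRYYASLRHYLN[TBA]VTRQR[ctYAD]
>37 PYY3-36 I->CIT L->AIB L->DAP
[CIT]KPEAPREDASPEE[AIB]NRYYASLRHY[DAP]NLVTRQR[ctYAD]
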