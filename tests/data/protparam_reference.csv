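accession,form,sequence,mw,pi,gravy,instability
UBIQ_HUMAN,mature chain,MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG,8564.7357,6.5616,-0.489474,36.0553
INSB_HUMAN,mature peptide,FVNQHLCGSHLVEALYLVCGERGFFYTPKT,3429.9208,6.9037,0.22,9.847
GLUC_HUMAN,mature peptide,HSQGTFTSDYSKYLDSRRAQDFVQWLMNT,3482.7469,6.7485,-0.989655,56.0276
MEL_APIME,mature peptide,GIGAVLKVLTTGLPALISWIKRKRQQ,2847.4471,12.0,0.273077,44.7308
ABETA42_HUMAN,mature peptide,DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA,4514.0381,5.3111,0.204762,18.1714
SMS14_HUMAN,mature peptide,AGCKNFFWKTFTSC,1639.8939,8.9091,0.028571,30.65
SUBP_HUMAN,mature peptide,RPKPQQFFGLM,1348.6146,11.0008,-0.7,47.9091
BRADY_HUMAN,mature peptide,RPPGFSPFR,1060.2085,12.0,-1.044444,121.9111
ANGT2_HUMAN,mature peptide,DRVYIHPF,1046.1785,6.7436,-0.325,25.8
GLP1_HUMAN,mature peptide,HAEGTFTSDVSSYLEGQAAKEFIAWLVKGR,3298.6142,5.5302,-0.23,17.6933
SYNTH01,synthetic,KVQCYSSDLIWPTKFNCTPSIYVSELAEQRYHILEDLFQKTRHTTIGQDEASQRSLNDDQLNSPNNHAKFKVFCGGQNSQKTEACRLEMEQKIHPICDYWQGYSRKGCWLFHNEVSRKPNPCKALHDDNEWNHNAYLSCLLWNLGHMKATVDNDQGQRSDWFANITTHYGMGWEAK,20572.7041,6.5224,-0.883523,50.2443
SYNTH02,synthetic,YVRVVMHSQICRGWFDTEENVEHSYMDAFDQDMQNETRRDDWIHLQYGWANPDDKYNWTLSADTSFMPVPKIKQVLFFRTDCNDTHDWEGEDACECNQIHMVVAEFFNKAIMDTCWCTWYTSPSDMMVLIPGDLKFIIHIQGWWLHMTQTMPGRFQVDPCRCWDYTNSSWGNCPENNLMSSLNWDDCQKSQHVSGIHEDWKIRNWSLIYRYDVPDNQALTGLKHWSDYVGTDYQQCVAFDSEWQAACPTFTCTWSQTAFDMRPVEREGRYPCPAVRECEYLSPNDWHNQPWDMKLDDGHKPPKKFNHAKLFNNRPQHSMKPIMRVWMMSHTLDCTCGHEHRATVIEPDIYYSHQRIPAFMEETYNTYDKICSKLEEWAFGLN,45502.5847,5.1318,-0.710209,42.4953
SYNTH03,synthetic,CFTPPQSCIMHTLSVMWNVHLMDIWPEHEAWKHNAGRPYPLSWRYSVDRKNQYYGRRHDASLYLYKSCNTWTAIADQRSVRTAFPVAMQAKVQFVHVGNIGVECHRTYGKDNYRNIWLDICFALPHKYSMGVFHWMRNQGFHEVGNSSKLYQTWSENDQYMKAYDAFCLMHCDICQFHIKADVAMLHKSTGHFLQFHWALREADWAEADPFNNTAVPESVGWLPYITHSPFKHCAHAERRRHVNDDQEMYAAYNDVVMPGCNGQTANFVGPNIQRNSYKMASMKCVIQDYEEVWFLRVIMRRSNDWVSCFRAYIRVIHPNKPWLEIIDEQHYFCSVGFEMLGALYQLDGGSVWYYYCDHNCTPMEGE,43299.6983,6.7602,-0.454768,50.9526
SYNTH04,synthetic,VNRGIKSSFWDVDGTEKKFRVVHMFFEWVSMLMMKDDYLYENFGADWHPLKMEYTRLEWHCHSPSSFWKPAYGCLDEPIWHRLQNLYHEQTAKVRYMQHWIRKNRMWKPHKKDCQQQAHESVFQDGDGQWFMRYPGPHYIQAKVPKWVHMLPHFWWTYRSSLLFPGGNKFTVEAHSTDSDIYEEKPWYCDSGVQDTEKNMQQYYMCRYHLKCQISTTKHRTLVDVCEMCCAKSAQTEDVTMTCIRGSMSLIFFSDCEETIYDQKIVYVEFQGRNNTRAAPLGKSTNIGMHNQCAFVPE,35677.2776,7.3135,-0.681879,36.8265
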