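/root/pkg/src/mitoquantsynth/mito.pypreprocess.pypipeline.pysynth/experiment.pyvesicle_coloc.pymito_events.py__init__.pygroup_stats.pysynth/vesicles.pysynth/__init__.py�   ����w'[(�j��Q��         �   ������y���Q��          �   ����AX�¯�,��Q��         �   e����~�s#V��Q��         �   7������p�ɂ���Q��         �   ���jbd
�l8���Q��          �   ����w'[(�j��Q��         io.py�����8bآi��Q��                                                                         racc.py����Ut���Q��          �   )���TFK�$.� ��Q��         cli.py��"5��T�ȋ�Q��         �   �������j�g9���Q��         �   ������_��uh��Q��         core.py�gMȄ���t��Q��         VI:Aw��dj57FVI:Aw��dj57 �   8�������      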