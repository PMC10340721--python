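/root/pkg/src/mitoquantsynth/experiment.pypreprocess.pypipeline.py__init__.pyvesicle_coloc.pymito_events.pysynth/mito.pygroup_stats.pysynth/vesicles.pysynth/__init__.py�   ����w'[(�jq�Q��         �   ������y���q�Q��          �   ����AX�¯�,q�Q��         �   c�����_��uhq�Q��         �   5������p�ɂ�q�Q��         �   ���jbd
�l8�q�Q��         �   �����~�s#Vq�Q��         io.py�����8bآiq�Q��                                                                         racc.py����Ut�q�Q��         �   /���TFK�$.� q�Q��         cli.py��"5��T��q�Q��         �   �������j�g9�q�Q��         �   ����w'[(�jq�Q��         core.py�gMȄ���tq�Q��         VjI:Aw��d75FVjI:Aw��d75 �   8�������      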